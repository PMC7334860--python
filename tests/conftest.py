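import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from assemblage.io import CommunityTable

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_table(counts, otu_ids=None, sample_ids=None) -> CommunityTable:
    arr = np.asarray(counts, dtype=np.int64)
    otus = otu_ids or [f"OTU{i+1}" for i in range(arr.shape[0])]
    samples = sample_ids or [f"S{j+1}" for j in range(arr.shape[1])]
    return CommunityTable(pd.DataFrame(arr, index=otus, columns=samples))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_table():
    # 4 OTUs x 3 samples with distinct abundance structure
    return make_table(
        [[5, 0, 2], [0, 3, 2], [1, 1, 1], [4, 6, 0]],
    )
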