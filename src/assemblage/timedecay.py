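"""Power-law time-decay of community similarity.

Community similarity S between pairs of samples separated by T hours is
modelled as S = c * T**w; on a log-log scale this is the linear regression
log10 S = log10 c + w * log10 T, and the slope w indexes the temporal
turnover rate of the community (more negative = faster turnover).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable

import numpy as np
from scipy import stats
from skbio import TreeNode

from assemblage.diversity import distance_matrix
from assemblage.io import CommunityTable, SampleMetadata

__all__ = [
    "SimilarityPair",
    "SimilarityPairSeries",
    "TimeDecayFit",
    "pairwise_similarity_series",
    "fit_time_decay",
]

METRICS = ("bray_curtis", "weighted_unifrac_normalized")


@dataclass(frozen=True)
class SimilarityPair:
    sample_a: str
    sample_b: str
    T: float  # hours between observations, > 0
    S: float  # similarity, in (0, 1]


@dataclass(frozen=True)
class SimilarityPairSeries:
    pairs: tuple[SimilarityPair, ...]
    n_excluded: int  # pairs dropped for T == 0 or S <= 0
    metric_name: str

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def T(self) -> np.ndarray:
        return np.array([p.T for p in self.pairs])

    @property
    def S(self) -> np.ndarray:
        return np.array([p.S for p in self.pairs])


@dataclass(frozen=True)
class TimeDecayFit:
    w: float  # scaling exponent (slope of the log-log regression)
    log10_c: float  # intercept
    r2: float
    p_value: float  # two-sided test of the slope
    n_pairs: int
    n_excluded: int
    metric_name: str


def pairwise_similarity_series(
    table: CommunityTable,
    metadata: SampleMetadata,
    metric: str = "bray_curtis",
    tree: TreeNode | None = None,
    sample_filter: Callable[[str], bool] | None = None,
) -> SimilarityPairSeries:
    """Similarity S = 1 - dissimilarity for all unordered sample pairs.

    T is the absolute difference in sampling hours. Pairs with T = 0 (same
    hour, log undefined) or S <= 0 are excluded and tallied rather than
    floored.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    samples = [
        s for s in table.sample_ids if sample_filter is None or sample_filter(s)
    ]
    if len(samples) < 2:
        raise ValueError("fewer than 2 samples pass the filter")
    metadata.require_samples(samples)
    sub = table.select_samples(samples).drop_empty_otus()
    if metric == "bray_curtis":
        dm = distance_matrix(sub, "bray_curtis")
    else:
        if tree is None:
            raise ValueError("phylogenetic metric requires a tree")
        dm = distance_matrix(sub, "weighted_unifrac", tree=tree, normalized=True)
    idx = {s: i for i, s in enumerate(dm.ids)}
    pairs: list[SimilarityPair] = []
    n_excluded = 0
    for a, b in combinations(samples, 2):
        t = abs(metadata.time_h(a) - metadata.time_h(b))
        s = 1.0 - float(dm.data[idx[a], idx[b]])
        if t <= 0 or s <= 0:
            n_excluded += 1
            continue
        pairs.append(SimilarityPair(a, b, t, s))
    if len(pairs) < 3:
        raise ValueError(
            f"fewer than 3 usable pairs ({len(pairs)}; {n_excluded} excluded)"
        )
    return SimilarityPairSeries(
        pairs=tuple(pairs), n_excluded=n_excluded, metric_name=metric
    )


def fit_time_decay(series: SimilarityPairSeries) -> TimeDecayFit:
    """Ordinary least squares of log10 S on log10 T."""
    if len(series) < 3:
        raise ValueError("time-decay fit requires at least 3 pairs")
    log_t = np.log10(series.T)
    log_s = np.log10(series.S)
    if np.ptp(log_t) == 0:
        raise ValueError("degenerate time design: zero variance in log10 T")
    res = stats.linregress(log_t, log_s)
    return TimeDecayFit(
        w=float(res.slope),
        log10_c=float(res.intercept),
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n_pairs=len(series),
        n_excluded=series.n_excluded,
        metric_name=series.metric_name,
    )
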