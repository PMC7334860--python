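"""Synthetic communities with known ground truth.

The generators emulate the data-generating assumptions of the modelled
study: a long-tailed (lognormal rank-abundance) source community, local
communities at the stationary law of the drift-immigration (neutral)
process with a known migration rate and fixed read depth, a minority of
injected non-neutral taxa (occupancy forced up or down), a multi-stage
sample time series whose similarity decays with time, and a random rooted
tree over the OTUs. Every generator is bit-reproducible given its seed.

The stationary Dirichlet-multinomial shortcut is the default local
community generator; the explicit forward (death-replacement) simulator
exists to validate that shortcut.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from assemblage.io import (
    STAGES,
    CommunityTable,
    SampleMetadata,
    TaxonomyMap,
    write_counts_table,
    write_metadata,
    write_newick,
    write_taxonomy,
)

__all__ = [
    "SimulationConfig",
    "StudyBundle",
    "generate_source",
    "simulate_local_communities",
    "inject_non_neutral",
    "simulate_succession",
    "random_tree",
    "synthetic_taxonomy",
    "simulate_study",
    "write_bundle",
]

MAX_CONCENTRATION = 1e6  # cap on N*m when drawing stationary compositions

# Per-stage migration-rate defaults for the study generator. The zoea
# values are the regime of interest (declining water-to-larvae dispersal
# after mouth opening); the pre-/post-zoea stages default to low exchange.
DEFAULT_STAGE_M = {
    "nauplius": 0.05,
    "zoeaI": 0.309,
    "zoeaII": 0.226,
    "zoeaIII": 0.042,
    "mysis": 0.03,
    "postlarvae": 0.02,
}

# Dense-to-sparse sampling hours over the 350 h nursery; water is not
# collected at hours 31, 206 and 254.
DEFAULT_STAGE_HOURS = {
    "nauplius": (0, 7, 14, 22, 31),
    "zoeaI": (36, 50, 64, 78, 92),
    "zoeaII": (108, 122, 136, 150),
    "zoeaIII": (158, 182, 206, 230),
    "mysis": (254, 278, 302),
    "postlarvae": (326, 350),
}
WATER_SKIP_HOURS = (31, 206, 254)

_FAMILY_LINEAGES = (
    "Bacteria;Proteobacteria;Alphaproteobacteria;Rhodobacterales;Rhodobacteraceae",
    "Bacteria;Bacteroidetes;Cytophagia;Cytophagales;Cyclobacteriaceae",
    "Bacteria;Bacteroidetes;Flavobacteriia;Flavobacteriales;Flavobacteriaceae",
    "Bacteria;Proteobacteria;Gammaproteobacteria;Vibrionales;Vibrionaceae",
    "Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacteriales;Enterobacteriaceae",
    "Bacteria;Bacteroidetes;Sphingobacteriia;Sphingobacteriales;Saprospiraceae",
    "Bacteria;Proteobacteria;Gammaproteobacteria;Alteromonadales;Pseudoalteromonadaceae",
    "Bacteria;Firmicutes;Bacilli;Lactobacillales;Lactobacillaceae",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the single-stage neutral-community simulation."""

    S: int = 300  # number of OTUs
    n_local: int = 50  # local-community samples
    N: int = 5000  # reads per sample (rarefaction depth)
    m_true: float = 0.3  # migration rate of the generating process
    source_sigma: float = 1.5  # lognormal shape of source abundances
    n_above: int = 10  # injected occupancy-boosted OTUs
    n_below: int = 10  # injected occupancy-suppressed OTUs
    seed: int = 0
    mode: str = "stationary"  # or "forward"

    def __post_init__(self) -> None:
        if self.S < 10:
            raise ValueError("S must be >= 10")
        if self.n_local < 5:
            raise ValueError("n_local must be >= 5")
        if self.N < 100:
            raise ValueError("N must be >= 100")
        if self.m_true <= 0:
            raise ValueError("m_true must be positive")
        if self.n_above + self.n_below >= self.S / 2:
            raise ValueError("too many injected non-neutral OTUs")
        if self.mode not in ("stationary", "forward"):
            raise ValueError("mode must be 'stationary' or 'forward'")


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _otu_ids(S: int) -> list[str]:
    return [f"OTU{i+1:04d}" for i in range(S)]


def _lognormal_composition(S: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    x = rng.lognormal(mean=0.0, sigma=sigma, size=S)
    return x / x.sum()


def generate_source(
    S: int, source_sigma: float = 1.5, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Lognormal source-community abundances, normalized to sum 1."""
    if S < 2:
        raise ValueError("S must be >= 2")
    if source_sigma <= 0:
        raise ValueError("source_sigma must be positive")
    return _lognormal_composition(S, source_sigma, _rng(seed))


def _stationary_composition(
    p: np.ndarray, N: int, m: float, rng: np.random.Generator
) -> np.ndarray:
    conc = min(N * m, MAX_CONCENTRATION)
    gam = rng.standard_gamma(np.maximum(conc * p, 1e-12))
    total = gam.sum()
    if total <= 0:  # extreme underflow: fall back to the modal taxon
        out = np.zeros_like(p)
        out[np.argmax(p)] = 1.0
        return out
    return gam / total


def _forward_sample(
    p: np.ndarray, N: int, m: float, rng: np.random.Generator, steps_factor: int
) -> np.ndarray:
    """One local community from the explicit death-replacement process."""
    S = p.size
    community = rng.choice(S, size=N, p=p)
    steps = steps_factor * N
    deaths = rng.integers(0, N, size=steps)
    immigrates = rng.random(steps) < m
    n_immig = int(immigrates.sum())
    immigrants = rng.choice(S, size=n_immig, p=p)
    local_picks = rng.integers(0, N, size=steps)
    k = 0
    for t in range(steps):
        if immigrates[t]:
            community[deaths[t]] = immigrants[k]
            k += 1
        else:
            community[deaths[t]] = community[local_picks[t]]
    return np.bincount(community, minlength=S)


def simulate_local_communities(
    p: np.ndarray,
    N: int,
    m_true: float,
    n_local: int,
    seed: int | np.random.Generator = 0,
    mode: str = "stationary",
    steps_factor: int = 20,
    otu_ids: list[str] | None = None,
    sample_prefix: str = "L",
) -> CommunityTable:
    """Local communities under drift + immigration at migration rate m.

    stationary: per sample, composition ~ Dirichlet(N*m*p) (the stationary
    law of the neutral process, concentration capped at 1e6), counts ~
    multinomial(N, composition). forward: run the discrete
    death-replacement update for steps_factor*N steps from a
    multinomial(N, p) start and emit the final counts.
    """
    rng = _rng(seed)
    p = np.asarray(p, dtype=float)
    ids = otu_ids if otu_ids is not None else _otu_ids(p.size)
    cols = {}
    for j in range(n_local):
        name = f"{sample_prefix}{j+1:03d}"
        if mode == "stationary":
            comp = _stationary_composition(p, N, m_true, rng)
            cols[name] = rng.multinomial(N, comp)
        elif mode == "forward":
            cols[name] = _forward_sample(p, N, m_true, rng, steps_factor)
        else:
            raise ValueError("mode must be 'stationary' or 'forward'")
    return CommunityTable(pd.DataFrame(cols, index=ids, dtype=np.int64))


def inject_non_neutral(
    table: CommunityTable,
    p: np.ndarray,
    n_above: int,
    n_below: int,
    seed: int | np.random.Generator = 0,
    above_count: int = 2,
) -> tuple[CommunityTable, list[str], list[str]]:
    """Create taxa the classifier must flag, by occupancy manipulation.

    above: OTUs drawn from the lowest decile of source abundance are forced
    present (a small constant count) in every sample. below: OTUs from the
    highest decile are zeroed everywhere. Sample totals are restored by
    adjusting the most abundant unaffected OTU, so depth stays exact.
    """
    rng = _rng(seed)
    p = np.asarray(p, dtype=float)
    ids = np.array(table.otu_ids)
    order = np.argsort(p, kind="stable")
    decile = max(p.size // 10, 1)
    low_pool = [i for i in order[:decile] if p[i] > 0]
    high_pool = list(order[-decile:])
    if len(low_pool) < n_above or len(high_pool) < n_below:
        raise ValueError("not enough candidate OTUs in the abundance deciles")
    above_idx = list(rng.choice(low_pool, size=n_above, replace=False)) if n_above else []
    high_pool = [i for i in high_pool if i not in set(above_idx)]
    below_idx = list(rng.choice(high_pool, size=n_below, replace=False)) if n_below else []

    df = table.data.copy()
    touched = set(above_idx) | set(below_idx)
    depth = int(table.sample_sums().iloc[0])
    for s in df.columns:
        col = df[s].to_numpy().copy()
        col[above_idx] = above_count
        col[below_idx] = 0
        delta = depth - col.sum()
        untouched = [
            i for i in np.argsort(col)[::-1] if i not in touched
        ]
        adjuster = untouched[0]
        if col[adjuster] + delta < 0:
            raise ValueError("cannot rebalance sample totals after injection")
        col[adjuster] += delta
        df[s] = col
    return (
        CommunityTable(df.astype(np.int64)),
        [str(ids[i]) for i in above_idx],
        [str(ids[i]) for i in below_idx],
    )


def simulate_succession(
    S: int = 200,
    n_timepoints: int = 12,
    samples_per_timepoint: int = 3,
    r: float = 0.3,
    N: int = 2000,
    seed: int | np.random.Generator = 0,
    source_sigma: float = 1.5,
    dt_hours: float | None = None,
    total_hours: float = 350.0,
) -> tuple[CommunityTable, SampleMetadata]:
    """A sample time series whose pairwise similarity decays with lag.

    The latent composition follows
    composition[t+1] = (1 - r) * composition[t] + r * fresh lognormal draw,
    and each time point is sampled to counts at depth N. r = 0 keeps the
    latent composition fixed (no turnover).
    """
    if not 0 <= r < 1:
        raise ValueError("replacement rate r must be in [0, 1)")
    rng = _rng(seed)
    ids = _otu_ids(S)
    if dt_hours is None:
        dt_hours = total_hours / max(n_timepoints - 1, 1)
    comp = _lognormal_composition(S, source_sigma, rng)
    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    stage_of = np.linspace(0, len(STAGES) - 1e-9, n_timepoints).astype(int)
    for t in range(n_timepoints):
        if t > 0 and r > 0:
            comp = (1 - r) * comp + r * _lognormal_composition(S, source_sigma, rng)
            comp = comp / comp.sum()
        for j in range(samples_per_timepoint):
            name = f"T{t:02d}R{j+1}"
            cols[name] = rng.multinomial(N, comp)
            meta_rows.append(
                {
                    "sample_id": name,
                    "habitat": "larvae",
                    "stage": STAGES[stage_of[t]],
                    "pond": f"P{j % 3 + 1}",
                    "time_h": t * dt_hours,
                }
            )
    table = CommunityTable(pd.DataFrame(cols, index=ids, dtype=np.int64))
    meta = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    return table, meta


def random_tree(
    otu_ids: list[str], seed: int | np.random.Generator = 0
) -> TreeNode:
    """Random binary rooted tree by sequential random joins.

    Branch lengths are exponential(1) draws; tips are the given OTU ids.
    """
    if len(otu_ids) < 2:
        raise ValueError("need >= 2 OTUs")
    rng = _rng(seed)
    nodes = [TreeNode(name=o) for o in otu_ids]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        a.length = float(rng.exponential(1.0))
        b.length = float(rng.exponential(1.0))
        parent = TreeNode(children=[a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (int(i), int(j))]
        nodes.append(parent)
    root = nodes[0]
    root.length = 0.0
    return root


def synthetic_taxonomy(otu_ids: list[str]) -> TaxonomyMap:
    """Synthetic lineages cycling through a fixed family list.

    Includes a Rhodobacteraceae-like family so category summaries can be
    exercised at the family rank. Genus is an explicit placeholder.
    """
    lineages = {}
    for i, otu in enumerate(otu_ids):
        fam_lineage = _FAMILY_LINEAGES[i % len(_FAMILY_LINEAGES)]
        names = fam_lineage.split(";")
        lineages[otu] = tuple(names) + (f"unclassified_{names[-1]}",)
    return TaxonomyMap(lineages)


# ---------------------------------------------------------------------------
# full multi-stage study generator


@dataclass(frozen=True)
class StudyBundle:
    table: CommunityTable
    metadata: SampleMetadata
    taxonomy: TaxonomyMap
    tree: TreeNode
    truth: dict = field(default_factory=dict)


def simulate_study(
    S: int = 500,
    depth: int = 22300,
    seed: int = 0,
    stage_m: dict[str, float] | None = None,
    stage_hours: dict[str, tuple[int, ...]] | None = None,
    ponds: int = 3,
    source_sigma: float = 1.5,
    stage_drift: float = 0.35,
    water_concentration: float = 5000.0,
) -> StudyBundle:
    """Emulate the full nursery design: 6 stages, larvae + water, 350 h.

    Per stage, the water (source) composition drifts from the previous
    stage's by ``stage_drift``; water samples are Dirichlet-multinomial
    replicates around it, and larval samples are stationary neutral-model
    draws with the stage's migration rate. Three ponds are sampled at
    every time point; water is absent at the study's three larvae-only
    hours.
    """
    rng = np.random.default_rng(seed)
    stage_m = dict(DEFAULT_STAGE_M if stage_m is None else stage_m)
    stage_hours = dict(DEFAULT_STAGE_HOURS if stage_hours is None else stage_hours)
    ids = _otu_ids(S)
    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    p_stage = _lognormal_composition(S, source_sigma, rng)
    truth_stage: dict[str, dict] = {}
    for stage in STAGES:
        if stage not in stage_hours:
            continue
        truth_stage[stage] = {"m_true": stage_m[stage]}
        for hour in stage_hours[stage]:
            for pond in range(1, ponds + 1):
                if hour not in WATER_SKIP_HOURS:
                    wcomp = _stationary_composition(
                        p_stage, int(water_concentration), 1.0, rng
                    )
                    wname = f"W{hour:03d}P{pond}"
                    cols[wname] = rng.multinomial(depth, wcomp)
                    meta_rows.append(
                        {
                            "sample_id": wname,
                            "habitat": "water",
                            "stage": stage,
                            "pond": f"P{pond}",
                            "time_h": float(hour),
                        }
                    )
                lcomp = _stationary_composition(p_stage, depth, stage_m[stage], rng)
                lname = f"L{hour:03d}P{pond}"
                cols[lname] = rng.multinomial(depth, lcomp)
                meta_rows.append(
                    {
                        "sample_id": lname,
                        "habitat": "larvae",
                        "stage": stage,
                        "pond": f"P{pond}",
                        "time_h": float(hour),
                    }
                )
        # drift the source pool into the next stage
        p_stage = (1 - stage_drift) * p_stage + stage_drift * _lognormal_composition(
            S, source_sigma, rng
        )
        p_stage = p_stage / p_stage.sum()
    table = CommunityTable(pd.DataFrame(cols, index=ids, dtype=np.int64))
    meta = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    tree = random_tree(ids, seed=rng)
    taxonomy = synthetic_taxonomy(ids)
    truth = {
        "seed": seed,
        "S": S,
        "depth": depth,
        "stage_m_true": {s: stage_m[s] for s in truth_stage},
        "source_sigma": source_sigma,
        "stage_drift": stage_drift,
    }
    return StudyBundle(table=table, metadata=meta, taxonomy=taxonomy, tree=tree, truth=truth)


def write_bundle(bundle: StudyBundle, outdir: str | Path) -> dict[str, Path]:
    """Write table/metadata/taxonomy/tree/ground-truth files for a bundle."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": out / "table.tsv",
        "metadata": out / "metadata.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "tree": out / "tree.nwk",
        "truth": out / "truth.json",
    }
    write_counts_table(bundle.table, paths["table"])
    write_metadata(bundle.metadata, paths["metadata"])
    write_taxonomy(bundle.taxonomy, paths["taxonomy"])
    write_newick(bundle.tree, paths["tree"])
    with paths["truth"].open("w") as fh:
        json.dump(bundle.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
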