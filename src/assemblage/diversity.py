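"""Alpha-diversity, beta-diversity, ordination, and group-separation tests.

Metrics are implemented directly from their definitions so the exact
conventions are pinned down in one place: Shannon in a configurable log
base (natural log by default), Faith's phylogenetic diversity including
the path to the root of the supplied tree, and weighted UniFrac in both
the raw branch-weighted form and the normalized form whose complement is a
similarity in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from skbio import DistanceMatrix, TreeNode

from assemblage.io import CommunityTable, relative_abundance

__all__ = [
    "richness",
    "shannon",
    "pielou",
    "faith_pd",
    "bray_curtis",
    "weighted_unifrac",
    "distance_matrix",
    "pcoa",
    "PCoAResult",
    "anosim",
    "AnosimResult",
    "alpha_diversity_table",
    "write_distance_matrix",
    "read_distance_matrix",
]


def _as_counts(x: Sequence[float] | np.ndarray) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D count vector")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    return arr


def richness(sample: Sequence[float] | np.ndarray) -> int:
    """Number of OTUs with a positive count."""
    return int(np.count_nonzero(_as_counts(sample)))


def shannon(sample: Sequence[float] | np.ndarray, log_base: float = np.e) -> float:
    """Shannon-Wiener index H = -sum q_i log(q_i) over detected OTUs."""
    arr = _as_counts(sample)
    total = arr.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero sample")
    q = arr[arr > 0] / total
    return float(-(q * (np.log(q) / np.log(log_base))).sum())


def pielou(sample: Sequence[float] | np.ndarray) -> float:
    """Pielou's evenness J = H / log(S); base-invariant, in (0, 1]."""
    s = richness(sample)
    if s < 2:
        raise ValueError("Pielou's evenness undefined for richness < 2")
    return shannon(sample) / np.log(s)


# ---------------------------------------------------------------------------
# tree-based metrics


def _tip_index(tree: TreeNode) -> dict[str, int]:
    return {tip.name: i for i, tip in enumerate(tree.tips())}


def _branch_incidence(tree: TreeNode) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
    """(lengths, incidence) over non-root nodes; incidence[b, t] = tip t below b."""
    tip_of = _tip_index(tree)
    n_tips = len(tip_of)
    below: dict[int, np.ndarray] = {}
    lengths: list[float] = []
    rows: list[np.ndarray] = []
    for node in tree.postorder(include_self=True):
        mask = np.zeros(n_tips, dtype=bool)
        if node.is_tip():
            mask[tip_of[node.name]] = True
        else:
            for child in node.children:
                mask |= below[id(child)]
        below[id(node)] = mask
        if not node.is_root():
            lengths.append(float(node.length or 0.0))
            rows.append(mask)
    return np.asarray(lengths), np.asarray(rows), tip_of


def _tip_vector(
    counts: Sequence[float] | np.ndarray | pd.Series,
    tip_of: dict[str, int],
    otu_ids: Sequence[str] | None,
    what: str,
) -> np.ndarray:
    """Map a count vector onto the tree's tip order; error on missing tips."""
    if isinstance(counts, pd.Series):
        otu_ids = list(counts.index)
        arr = counts.to_numpy(dtype=float)
    else:
        arr = _as_counts(counts)
        if otu_ids is None:
            raise ValueError(f"{what}: otu_ids required for unlabelled vectors")
    out = np.zeros(len(tip_of))
    for otu, v in zip(otu_ids, arr):
        if v > 0:
            if otu not in tip_of:
                raise KeyError(f"{what}: observed OTU {otu!r} is not a tree tip")
            out[tip_of[otu]] = v
    return out


def faith_pd(
    sample: Sequence[float] | pd.Series,
    tree: TreeNode,
    otu_ids: Sequence[str] | None = None,
) -> float:
    """Faith's PD: total branch length of the minimal rooted subtree
    spanning the observed OTUs (root path included)."""
    lengths, incidence, tip_of = _branch_incidence(tree)
    vec = _tip_vector(sample, tip_of, otu_ids, "faith_pd")
    present = vec > 0
    if not present.any():
        return 0.0
    used = incidence[:, present].any(axis=1)
    return float(lengths[used].sum())


def bray_curtis(
    x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray
) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min)/(sum x + sum y)."""
    ax, ay = _as_counts(x), _as_counts(y)
    if ax.shape != ay.shape:
        raise ValueError("vectors must have equal length")
    tx, ty = ax.sum(), ay.sum()
    if tx <= 0 or ty <= 0:
        raise ValueError("Bray-Curtis undefined for a zero-total vector")
    return float(1.0 - 2.0 * np.minimum(ax, ay).sum() / (tx + ty))


def weighted_unifrac(
    x: Sequence[float] | pd.Series,
    y: Sequence[float] | pd.Series,
    tree: TreeNode,
    normalized: bool = False,
    otu_ids: Sequence[str] | None = None,
) -> float:
    """Weighted UniFrac: sum_b l_b |A_b - B_b| over branches.

    A_b / B_b are the fractions of each sample's reads descending branch b.
    The normalized form divides by sum_b l_b (A_b + B_b) and lies in [0,1].
    """
    lengths, incidence, tip_of = _branch_incidence(tree)
    vx = _tip_vector(x, tip_of, otu_ids, "weighted_unifrac")
    vy = _tip_vector(y, tip_of, otu_ids, "weighted_unifrac")
    tx, ty = vx.sum(), vy.sum()
    if tx <= 0 or ty <= 0:
        raise ValueError("weighted UniFrac undefined for a zero-total vector")
    inc = incidence.astype(float)
    a = inc @ (vx / tx)
    b = inc @ (vy / ty)
    raw = float((lengths * np.abs(a - b)).sum())
    if not normalized:
        return raw
    denom = float((lengths * (a + b)).sum())
    if denom <= 0:
        return 0.0
    return raw / denom


# ---------------------------------------------------------------------------
# distance matrices


def distance_matrix(
    table: CommunityTable,
    metric: str,
    tree: TreeNode | None = None,
    normalized: bool = False,
) -> DistanceMatrix:
    """Pairwise dissimilarity matrix over the table's samples."""
    props = relative_abundance(table).to_numpy()
    ids = table.sample_ids
    n = len(ids)
    out = np.zeros((n, n))
    if metric == "bray_curtis":
        counts = table.counts.astype(float)
        for i, j in combinations(range(n), 2):
            out[i, j] = out[j, i] = bray_curtis(counts[:, i], counts[:, j])
    elif metric == "weighted_unifrac":
        if tree is None:
            raise ValueError("weighted_unifrac requires a tree")
        lengths, incidence, tip_of = _branch_incidence(tree)
        vecs = np.zeros((len(tip_of), n))
        for j in range(n):
            vecs[:, j] = _tip_vector(
                pd.Series(props[:, j], index=table.otu_ids), tip_of, None, metric
            )
        frac = incidence.astype(float) @ vecs  # branch x sample
        for i, j in combinations(range(n), 2):
            raw = (lengths * np.abs(frac[:, i] - frac[:, j])).sum()
            if normalized:
                denom = (lengths * (frac[:, i] + frac[:, j])).sum()
                out[i, j] = out[j, i] = raw / denom if denom > 0 else 0.0
            else:
                out[i, j] = out[j, i] = raw
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(out, ids=ids)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=list(df.index))


# ---------------------------------------------------------------------------
# ordination


@dataclass(frozen=True)
class PCoAResult:
    """Classical multidimensional scaling of a dissimilarity matrix."""

    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # per retained axis, vs sum of positives
    warnings: tuple[str, ...] = field(default_factory=tuple)


def pcoa(dm: DistanceMatrix, k: int = 2) -> PCoAResult:
    """Principal coordinates analysis by double-centering -0.5 D^2.

    Axes with non-positive eigenvalues carry no real coordinates and are
    truncated (with a warning record if fewer than ``k`` remain); negative
    eigenvalues are reported unmodified rather than corrected.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d * d) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval).max(), 1.0) * 1e-12
    n_pos = int((eigval > tol).sum())
    warns: list[str] = []
    k_eff = min(k, n_pos)
    if k_eff < k:
        warns.append(
            f"requested {k} axes but only {n_pos} positive eigenvalues; truncated"
        )
    coords = eigvec[:, :k_eff] * np.sqrt(eigval[:k_eff])
    pos_sum = eigval[:n_pos].sum() if n_pos else 1.0
    prop = eigval[:k_eff] / pos_sum
    frame = pd.DataFrame(
        coords, index=list(dm.ids), columns=[f"PC{i+1}" for i in range(k_eff)]
    )
    return PCoAResult(
        coordinates=frame,
        eigenvalues=eigval,
        proportion_explained=prop,
        warnings=tuple(warns),
    )


# ---------------------------------------------------------------------------
# ANOSIM


@dataclass(frozen=True)
class AnosimResult:
    R: float
    p: float
    n_perm: int


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    # divisor n(n-1)/4 = M/2 over M = n(n-1)/2 pairs: scales R to [-1, 1]
    m = ranks.size
    r_within = ranks[within].mean()
    r_between = ranks[~within].mean()
    return float((r_between - r_within) / (m / 2.0))


def anosim(
    dm: DistanceMatrix,
    groups: Sequence[str],
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    exact: bool = False,
) -> AnosimResult:
    """Rank-based test that between-group dissimilarities exceed within-group.

    R = (mean rank between - mean rank within) / (M/4) with M = n(n-1)/2
    pairwise distances, average ranks on ties; the p-value is the add-one
    permutation tail (1 + #{R_perm >= R_obs}) / (n_perm + 1). With
    ``exact`` all label orderings are enumerated instead (small n only)
    and p is the exact fraction with R_perm >= R_obs, identity included.
    """
    labels = np.asarray(groups)
    n = len(dm.ids)
    if labels.shape[0] != n:
        raise ValueError("one group label per sample required")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM requires at least two groups")
    if counts.min() < 2:
        small = uniq[counts < 2]
        raise ValueError(f"group(s) of size 1 not allowed: {list(small)}")
    iu = np.triu_indices(n, k=1)
    dists = np.asarray(dm.data)[iu]
    ranks = rankdata(dists)  # average ranks on ties
    within = labels[iu[0]] == labels[iu[1]]
    r_obs = _anosim_r(ranks, within)
    if exact:
        if n > 9:
            raise ValueError("exact enumeration limited to n <= 9 samples")
        from itertools import permutations as _perms

        hits = total = 0
        for perm in _perms(labels):
            arr = np.asarray(perm)
            w = arr[iu[0]] == arr[iu[1]]
            hits += _anosim_r(ranks, w) >= r_obs - 1e-12
            total += 1
        return AnosimResult(R=r_obs, p=hits / total, n_perm=total)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        w = perm[iu[0]] == perm[iu[1]]
        if _anosim_r(ranks, w) >= r_obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return AnosimResult(R=r_obs, p=p, n_perm=n_perm)


# ---------------------------------------------------------------------------
# convenience


def alpha_diversity_table(
    table: CommunityTable, tree: TreeNode | None = None
) -> pd.DataFrame:
    """Per-sample richness, Shannon, Pielou (NaN below richness 2), Faith PD."""
    rows = []
    lengths = incidence = tip_of = None
    if tree is not None:
        lengths, incidence, tip_of = _branch_incidence(tree)
    for s in table.sample_ids:
        counts = table.sample(s)
        s_rich = richness(counts)
        row = {
            "sample_id": s,
            "richness": s_rich,
            "shannon": shannon(counts) if s_rich else np.nan,
            "pielou": pielou(counts) if s_rich >= 2 else np.nan,
        }
        if tree is not None:
            vec = _tip_vector(counts, tip_of, None, "faith_pd")
            present = vec > 0
            row["faith_pd"] = (
                float(lengths[incidence[:, present].any(axis=1)].sum())
                if present.any()
                else 0.0
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")
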