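"""Sloan neutral community model: fit, classification, model comparison.

The model treats each local community (here, the bacterial community of
one larva sample) as a fixed-size assembly of N individuals undergoing
random death and replacement, where a death is replaced by an immigrant
from a source metacommunity with probability m (the migration rate) and
by local reproduction otherwise. At stationarity the relative abundance
of a taxon with source abundance p follows a Beta(N*m*p, N*m*(1-p))
distribution, so the probability of detecting the taxon at all (relative
abundance above a detection limit d, one read by default) is

    freq(p) = 1 - I_d(N*m*p, N*m*(1-p))

with I the regularized incomplete beta function. Fitting freq to the
observed occurrence frequencies across local samples by non-linear least
squares yields m; taxa whose observed frequency falls outside a 95% band
around the fitted curve are flagged as above-prediction (favoured by
selection or dispersal) or below-prediction (selected against or
dispersal-limited). A one-parameter-free binomial sampling model
(freq = 1 - (1-p)^N, pure subsampling of the source) is compared by AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import betaincc

from assemblage.io import CommunityTable, TaxonomyMap, relative_abundance

__all__ = [
    "NeutralFit",
    "OtuNeutralRecord",
    "CategorySummary",
    "FitMResult",
    "occurrence_frequency",
    "source_abundance",
    "predict_freq",
    "fit_m",
    "prediction_band",
    "wilson_interval",
    "classify",
    "compare_models_aic",
    "fit_ncm",
    "category_summary",
]

M_BOUNDS = (1e-6, 1e3)
MULTISTART = (0.01, 0.1, 0.5)
CATEGORIES = ("above", "neutral", "below")


# ---------------------------------------------------------------------------
# building blocks


def occurrence_frequency(
    table: CommunityTable, local_samples: Iterable[str]
) -> pd.Series:
    """Fraction of local samples in which each OTU is detected (>= 1 read)."""
    samples = list(local_samples)
    if not samples:
        raise ValueError("empty local sample set")
    if len(samples) < 2:
        raise ValueError("occurrence frequency requires >= 2 local samples")
    sub = table.select_samples(samples)
    return (sub.data > 0).sum(axis=1) / len(samples)


def source_abundance(
    table: CommunityTable, source_samples: Iterable[str]
) -> pd.Series:
    """Mean per-sample relative abundance of each OTU in the source set."""
    samples = list(source_samples)
    if not samples:
        raise ValueError("empty source sample set")
    sub = table.select_samples(samples)
    return relative_abundance(sub).mean(axis=1)


def predict_freq(
    p: np.ndarray | float, N: float, m: float, d: float
) -> np.ndarray | float:
    """Stationary detection probability of the neutral model.

    freq = 1 - F_Beta(d; N*m*p, N*m*(1-p)); taxa with p <= 0 return 0 by
    convention (they are never fit on).
    """
    if N * m <= 0:
        raise ValueError("N*m must be positive")
    if not 0 < d < 1:
        raise ValueError("detection limit d must be in (0, 1)")
    p_arr = np.asarray(p, dtype=float)
    scalar = p_arr.ndim == 0
    p_arr = np.atleast_1d(p_arr)
    out = np.zeros_like(p_arr)
    ok = (p_arr > 0) & (p_arr < 1)
    nm = N * m
    out[ok] = betaincc(nm * p_arr[ok], nm * (1.0 - p_arr[ok]), d)
    out[p_arr >= 1] = 1.0
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if scalar else out


def _sse(m: float, p: np.ndarray, f: np.ndarray, N: float, d: float) -> float:
    return float(np.sum((f - predict_freq(p, N, m, d)) ** 2))


@dataclass(frozen=True)
class FitMResult:
    m: float
    r2: float
    sse: float
    sst: float
    n_points: int


def fit_m(
    freq_obs: Sequence[float] | np.ndarray,
    p: Sequence[float] | np.ndarray,
    N: float,
    d: float | None = None,
    m0: float = 0.1,
) -> FitMResult:
    """Estimate the migration rate by bounded non-linear least squares.

    Minimizes sum_i (freq_obs_i - predict_freq(p_i))^2 over
    m in (1e-6, 1e3), multi-starting from {m0} | {0.01, 0.1, 0.5} and
    keeping the best objective. r2 = 1 - SSE/SST may be negative ("no
    fit"); it is reported raw.
    """
    f = np.asarray(freq_obs, dtype=float)
    pp = np.asarray(p, dtype=float)
    if f.shape != pp.shape:
        raise ValueError("freq_obs and p must align")
    keep = pp > 0
    f, pp = f[keep], pp[keep]
    if int(((pp > 0) & (f > 0)).sum()) < 10:
        raise ValueError("need >= 10 OTUs with p > 0 and freq_obs > 0")
    if d is None:
        d = 1.0 / N
    starts = sorted({float(m0), *MULTISTART})
    best = None
    errors = []
    for start in starts:
        try:
            res = optimize.least_squares(
                lambda x: f - predict_freq(pp, N, x[0], d),
                x0=[np.clip(start, *M_BOUNDS)],
                bounds=([M_BOUNDS[0]], [M_BOUNDS[1]]),
                method="trf",
            )
        except Exception as exc:  # pragma: no cover - optimizer failure path
            errors.append(f"start {start}: {exc}")
            continue
        sse = float(np.sum(res.fun**2))
        if res.success and (best is None or sse < best[1]):
            best = (float(res.x[0]), sse)
        elif not res.success:
            errors.append(f"start {start}: {res.message} (sse={sse:.4g})")
    if best is None:
        raise RuntimeError(
            "migration-rate fit failed from all starts: " + "; ".join(errors)
        )
    m_hat, sse = best
    sst = float(np.sum((f - f.mean()) ** 2))
    if sst > 0:
        r2 = 1.0 - sse / sst
    else:
        r2 = 1.0 if sse == 0 else float("-inf")
    return FitMResult(m=m_hat, r2=r2, sse=sse, sst=sst, n_points=f.size)


# ---------------------------------------------------------------------------
# prediction bands


def wilson_interval(
    freq: np.ndarray | float, n: int, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Wilson score interval for a proportion ``freq`` at denominator n."""
    from scipy.stats import norm

    z = norm.ppf(1 - alpha / 2)
    f = np.asarray(freq, dtype=float)
    denom = 1 + z**2 / n
    center = (f + z**2 / (2 * n)) / denom
    half = (z / denom) * np.sqrt(f * (1 - f) / n + z**2 / (4 * n**2))
    return np.clip(center - half, 0, 1), np.clip(center + half, 0, 1)


def _bootstrap_refit_grid(
    p_fit: np.ndarray,
    f_fit: np.ndarray,
    weights: np.ndarray,
    N: float,
    d: float,
    n_grid: int = 400,
) -> np.ndarray:
    """Refit m for every bootstrap replicate at once.

    ``weights`` is (n_boot, n_fit): multiplicities of each OTU in the
    resample. The per-OTU squared errors are precomputed on one fine
    log10(m) grid, every replicate's weighted objective is a matrix
    product against them, and the grid minimum is refined by parabolic
    interpolation of the objective in log10(m). Residual resolution
    (< 1% in m) is far below the band's Monte-Carlo noise.
    """
    lo, hi = np.log10(M_BOUNDS[0]), np.log10(M_BOUNDS[1])
    grid = np.logspace(lo, hi, n_grid)
    step = (hi - lo) / (n_grid - 1)
    preds = np.stack([predict_freq(p_fit, N, g, d) for g in grid])  # (G, n)
    sq = (f_fit[None, :] - preds) ** 2
    obj = weights @ sq.T  # (n_boot, G)
    arg = np.argmin(obj, axis=1)
    inner = np.clip(arg, 1, n_grid - 2)
    o_l = obj[np.arange(obj.shape[0]), inner - 1]
    o_c = obj[np.arange(obj.shape[0]), inner]
    o_r = obj[np.arange(obj.shape[0]), inner + 1]
    denom = o_l - 2 * o_c + o_r
    with np.errstate(divide="ignore", invalid="ignore"):
        offset = 0.5 * (o_l - o_r) / denom
    offset = np.where((denom > 0) & (arg == inner), offset, 0.0)
    offset = np.clip(offset, -0.5, 0.5)
    return np.power(10.0, lo + (inner + offset) * step)


def prediction_band(
    freq_obs: Sequence[float] | np.ndarray,
    p: Sequence[float] | np.ndarray,
    N: float,
    d: float,
    n_local: int,
    m_hat: float,
    p_eval: Sequence[float] | np.ndarray | None = None,
    method: str = "bootstrap",
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    resample: str = "otus",
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """95% band around the fitted occurrence-frequency curve.

    bootstrap: resample the fitted OTUs with replacement ``n_boot`` times,
    refit m each time, and take the 2.5/97.5 percentiles at each evaluation
    abundance of the predicted frequency combined (by simulation) with the
    binomial sampling noise of estimating a frequency from ``n_local``
    samples. wilson: Wilson score interval on the fitted curve with
    denominator ``n_local``. Returns (ci_low, ci_high, warnings); the band
    always contains the point prediction.
    """
    warns: list[str] = []
    f_fit = np.asarray(freq_obs, dtype=float)
    p_fit = np.asarray(p, dtype=float)
    eval_p = p_fit if p_eval is None else np.asarray(p_eval, dtype=float)
    point = predict_freq(eval_p, N, m_hat, d)
    if method == "wilson":
        lo, hi = wilson_interval(point, n_local, alpha)
    elif method == "bootstrap":
        if n_boot < 100:
            warns.append(f"n_boot={n_boot} < 100: band will be noisy")
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        n_fit = f_fit.size
        if resample == "otus":
            weights = rng.multinomial(
                n_fit, np.full(n_fit, 1.0 / n_fit), size=n_boot
            ).astype(float)
        elif resample == "samples":
            # occurrence frequencies re-drawn as binomial at n_local: a
            # parametric stand-in for resampling the local samples
            weights = np.ones((n_boot, n_fit))
            f_res = rng.binomial(n_local, f_fit, size=(n_boot, n_fit)) / n_local
        else:
            raise ValueError(f"unknown resample mode {resample!r}")
        if resample == "otus":
            m_boot = _bootstrap_refit_grid(p_fit, f_fit, weights, N, d)
        else:
            m_boot = np.array(
                [fit_m(fr, p_fit, N, d, m0=m_hat).m for fr in f_res]
            )
        nm = N * m_boot[:, None]
        with np.errstate(invalid="ignore"):
            pred = betaincc(
                np.maximum(nm * eval_p[None, :], 1e-300),
                np.maximum(nm * (1.0 - eval_p[None, :]), 1e-300),
                d,
            )
        pred = np.clip(np.nan_to_num(pred), 0.0, 1.0)
        sim = rng.binomial(n_local, pred) / n_local
        # outward-rounded percentiles: the simulated band distribution is
        # discrete (multiples of 1/n_local), so interpolated quantiles
        # would undercover; round outward to attainable values instead
        lo = np.percentile(sim, 100 * alpha / 2, axis=0, method="lower")
        hi = np.percentile(sim, 100 * (1 - alpha / 2), axis=0, method="higher")
    else:
        raise ValueError(f"unknown band method {method!r}")
    lo = np.minimum(lo, point)
    hi = np.maximum(hi, point)
    return lo, hi, warns


def classify(
    freq_obs: Sequence[float] | np.ndarray,
    ci_low: Sequence[float] | np.ndarray,
    ci_high: Sequence[float] | np.ndarray,
) -> np.ndarray:
    """Three-way labels by strict band comparison; boundary ties are neutral."""
    f = np.asarray(freq_obs, dtype=float)
    lo = np.asarray(ci_low, dtype=float)
    hi = np.asarray(ci_high, dtype=float)
    out = np.full(f.shape, "neutral", dtype=object)
    out[f > hi] = "above"
    out[f < lo] = "below"
    return out


# ---------------------------------------------------------------------------
# AIC comparison with the binomial sampling model


def binomial_freq(p: np.ndarray | float, N: float) -> np.ndarray | float:
    """Detection probability under pure binomial subsampling of the source."""
    p_arr = np.asarray(p, dtype=float)
    out = -np.expm1(N * np.log1p(-np.clip(p_arr, 0.0, 1.0 - 1e-15)))
    return float(out) if np.isscalar(p) else out


def _gaussian_aic(residuals: np.ndarray, k: int) -> float:
    n = residuals.size
    sigma2 = float(np.mean(residuals**2))
    if sigma2 <= 0:
        raise ValueError("degenerate: zero residual variance")
    lnl = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    return 2 * k - 2 * lnl


def compare_models_aic(
    freq_obs: Sequence[float] | np.ndarray,
    p: Sequence[float] | np.ndarray,
    N: float,
    d: float,
    m: float,
) -> dict[str, float]:
    """Gaussian-residual ML AIC of the neutral fit vs. binomial sampling.

    k = 2 for the neutral model (m and the residual scale) and k = 1 for
    the binomial model (residual scale only; its curve has no free
    parameter).
    """
    f = np.asarray(freq_obs, dtype=float)
    pp = np.asarray(p, dtype=float)
    res_neutral = f - predict_freq(pp, N, m, d)
    res_binom = f - binomial_freq(pp, N)
    return {
        "aic_neutral": _gaussian_aic(res_neutral, k=2),
        "aic_binomial": _gaussian_aic(res_binom, k=1),
    }


# ---------------------------------------------------------------------------
# record types and the orchestrating fit


@dataclass(frozen=True)
class OtuNeutralRecord:
    otu_id: str
    p: float
    freq_obs: float
    freq_pred: float
    ci_low: float
    ci_high: float
    category: str
    mean_local_abundance: float
    in_objective: bool  # False for source-present OTUs absent from all locals


@dataclass(frozen=True)
class NeutralFit:
    m: float
    N: int
    d: float
    r2: float
    aic_neutral: float
    aic_binomial: float
    n_local: int
    n_otus_fit: int
    source_mode: str  # "external" | "self"
    band_method: str
    records: tuple[OtuNeutralRecord, ...]
    n_excluded_absent: int = 0
    seed: int | None = None
    warnings: tuple[str, ...] = field(default_factory=tuple)

    @property
    def degenerate(self) -> bool:
        return any("degenerate" in w for w in self.warnings)

    def category_counts(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for r in self.records:
            out[r.category] += 1
        return out

    def records_frame(self, taxonomy: TaxonomyMap | None = None) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "otu_id": r.otu_id,
                "p": r.p,
                "freq_obs": r.freq_obs,
                "freq_pred": r.freq_pred,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "category": r.category,
                "mean_local_abundance": r.mean_local_abundance,
            }
            if taxonomy is not None:
                row["lineage"] = taxonomy.lineage_string(r.otu_id)
            rows.append(row)
        return pd.DataFrame(rows)

    def report_row(self) -> dict[str, object]:
        return {
            "source_mode": self.source_mode,
            "m": self.m,
            "N": self.N,
            "d": self.d,
            "r2": self.r2,
            "aic_neutral": self.aic_neutral,
            "aic_binomial": self.aic_binomial,
            "n_local": self.n_local,
            "n_otus_fit": self.n_otus_fit,
            "band_method": self.band_method,
            "seed": self.seed,
        }


def fit_ncm(
    table: CommunityTable,
    local_samples: Iterable[str],
    source: str | Iterable[str] = "self",
    N: int | None = None,
    d: float | None = None,
    band_method: str = "bootstrap",
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    m0: float = 0.1,
    include_locally_absent: bool = True,
) -> NeutralFit:
    """Fit the neutral model end to end on a rarefied table.

    External mode (``source`` = a disjoint sample set, e.g. rearing-water
    samples): the least-squares objective uses OTUs present in both local
    and source sets; source-present OTUs absent from every local sample are
    excluded from the objective but, when ``include_locally_absent``,
    retained in the record set and classified against the band (occupancy
    zero at high source abundance is the below-prediction signal). Self
    mode: the pooled local samples are their own metacommunity and every
    OTU present in >= 1 local sample enters the fit.

    N defaults to the (common) post-rarefaction sample depth and the
    detection limit d to 1/N (one read).
    """
    local = list(local_samples)
    if len(local) < 2:
        raise ValueError("need >= 2 local samples")
    self_mode = isinstance(source, str) and source == "self"
    if self_mode:
        source_set = local
    else:
        source_set = list(source)  # type: ignore[arg-type]
        overlap = set(local) & set(source_set)
        if overlap:
            raise ValueError(
                f"local and source sample sets overlap: {sorted(overlap)}"
            )
        if not source_set:
            raise ValueError("empty source sample set")
    warns: list[str] = []
    local_sums = table.select_samples(local).sample_sums()
    if N is None:
        uniq = sorted(set(int(v) for v in local_sums))
        if len(uniq) > 1:
            warns.append(
                f"unequal local sample depths {uniq[0]}..{uniq[-1]}; "
                "using the mean as N (rarefy first for exact depths)"
            )
            N = int(round(float(local_sums.mean())))
        else:
            N = uniq[0]
    if d is None:
        d = 1.0 / N

    freq = occurrence_frequency(table, local)
    p = source_abundance(table, source_set)
    mean_local = relative_abundance(table.select_samples(local)).mean(axis=1)

    in_source = p > 0
    in_local = freq > 0
    obj_mask = in_source & in_local
    if self_mode:
        record_mask = obj_mask
        n_excluded_absent = 0
    else:
        record_mask = in_source & (in_local | bool(include_locally_absent))
        n_excluded_absent = int((in_source & ~in_local).sum())
    obj_ids = list(freq.index[obj_mask])
    if len(obj_ids) < 10:
        raise ValueError(
            f"fewer than 10 eligible OTUs ({len(obj_ids)}) for the fit"
        )
    f_fit = freq[obj_ids].to_numpy()
    p_fit = p[obj_ids].to_numpy()
    if np.ptp(f_fit) == 0:
        warns.append(
            "degenerate design: occurrence frequency constant across fitted OTUs"
        )
    mres = fit_m(f_fit, p_fit, N, d, m0=m0)

    rec_ids = list(freq.index[record_mask])
    p_rec = p[rec_ids].to_numpy()
    lo, hi, band_warns = prediction_band(
        f_fit,
        p_fit,
        N,
        d,
        n_local=len(local),
        m_hat=mres.m,
        p_eval=p_rec,
        method=band_method,
        n_boot=n_boot,
        alpha=alpha,
        seed=seed,
    )
    warns.extend(band_warns)
    f_rec = freq[rec_ids].to_numpy()
    pred_rec = predict_freq(p_rec, N, mres.m, d)
    cats = classify(f_rec, lo, hi)
    obj_set = set(obj_ids)
    records = tuple(
        OtuNeutralRecord(
            otu_id=o,
            p=float(p_rec[i]),
            freq_obs=float(f_rec[i]),
            freq_pred=float(pred_rec[i]),
            ci_low=float(lo[i]),
            ci_high=float(hi[i]),
            category=str(cats[i]),
            mean_local_abundance=float(mean_local[o]),
            in_objective=o in obj_set,
        )
        for i, o in enumerate(rec_ids)
    )
    try:
        aics = compare_models_aic(f_fit, p_fit, N, d, mres.m)
    except ValueError as exc:
        # degenerate designs (e.g. every OTU in every sample) leave no
        # residual variance; flag instead of failing the whole fit
        warns.append(f"degenerate: {exc}")
        aics = {"aic_neutral": float("nan"), "aic_binomial": float("nan")}
    return NeutralFit(
        m=mres.m,
        N=int(N),
        d=float(d),
        r2=mres.r2,
        aic_neutral=aics["aic_neutral"],
        aic_binomial=aics["aic_binomial"],
        n_local=len(local),
        n_otus_fit=len(records),
        source_mode="self" if self_mode else "external",
        band_method=band_method,
        records=records,
        n_excluded_absent=n_excluded_absent,
        seed=seed if isinstance(seed, int) else None,
        warnings=tuple(warns),
    )


# ---------------------------------------------------------------------------
# category summaries


@dataclass(frozen=True)
class CategorySummary:
    rank: str
    otu_count: dict[str, int]
    cumulative_relative_abundance: dict[str, float]
    taxon_breakdown: dict[str, dict[str, float]]  # category -> taxon -> abund
    unfit_abundance: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat in CATEGORIES:
            for taxon, ab in sorted(self.taxon_breakdown[cat].items()):
                rows.append(
                    {"category": cat, "taxon": taxon, "cumulative_abundance": ab}
                )
        return pd.DataFrame(rows)


def category_summary(
    fit: NeutralFit,
    table: CommunityTable,
    local_samples: Iterable[str],
    taxonomy: TaxonomyMap,
    rank: str = "family",
) -> CategorySummary:
    """Cumulative mean local abundance of the three categories, by taxon.

    The three category totals plus the abundance of OTUs outside the fit
    sum to 1 (mean relative abundances across the local samples partition
    the whole community).
    """
    local = list(local_samples)
    mean_local = relative_abundance(table.select_samples(local)).mean(axis=1)
    counts = {c: 0 for c in CATEGORIES}
    totals = {c: 0.0 for c in CATEGORIES}
    breakdown: dict[str, dict[str, float]] = {c: {} for c in CATEGORIES}
    fitted = set()
    for r in fit.records:
        fitted.add(r.otu_id)
        counts[r.category] += 1
        ab = float(mean_local.get(r.otu_id, 0.0))
        totals[r.category] += ab
        taxon = taxonomy.name_at(r.otu_id, rank)
        breakdown[r.category][taxon] = breakdown[r.category].get(taxon, 0.0) + ab
    unfit = float(mean_local[~mean_local.index.isin(fitted)].sum())
    return CategorySummary(
        rank=rank,
        otu_count=counts,
        cumulative_relative_abundance=totals,
        taxon_breakdown=breakdown,
        unfit_abundance=unfit,
    )
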