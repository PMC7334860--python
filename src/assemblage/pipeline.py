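"""Stage-wise orchestration of the succession-and-assembly analysis.

One :func:`run_stagewise` call reproduces the study design end to end on
any conforming input bundle: joint rarefaction, per-sample alpha
diversity, larvae/water shared-OTU partitions, neutral-model fits per
stage in external (water source) and self (larval metacommunity) modes
with category summaries, cross-stage ordination and ANOSIM, and the
taxonomic and phylogenetic time-decay fits — all written as TSVs plus a
machine-readable manifest sufficient to re-run bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import assemblage
from assemblage.diversity import (
    alpha_diversity_table,
    anosim,
    distance_matrix,
    pcoa,
    write_distance_matrix,
)
from assemblage.io import (
    STAGES,
    CommunityTable,
    rarefy,
    read_counts_table,
    read_metadata,
    read_newick,
    read_taxonomy,
    shared_otu_partition,
)
from assemblage.neutral import category_summary, fit_ncm
from assemblage.timedecay import fit_time_decay, pairwise_similarity_series

log = logging.getLogger("assemblage")

FLOAT_FMT = "%.10g"

MIN_LARVAE_PER_STAGE = 5


@dataclass
class RunConfig:
    table: str
    metadata: str
    taxonomy: str | None = None
    tree: str | None = None
    depth: int = 22300
    stages: tuple[str, ...] = STAGES
    source_modes: tuple[str, ...] = ("external", "self")
    band_method: str = "bootstrap"
    n_boot: int = 1000
    alpha: float = 0.05
    timedecay_metrics: tuple[str, ...] = (
        "bray_curtis",
        "weighted_unifrac_normalized",
    )
    anosim_permutations: int = 999
    summary_ranks: tuple[str, ...] = ("phylum", "family")
    seed: int = 0
    outdir: str = "results/run"

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage(s): {sorted(bad)}")
        self.stages = tuple(self.stages)
        self.source_modes = tuple(self.source_modes)
        self.timedecay_metrics = tuple(self.timedecay_metrics)
        self.summary_ranks = tuple(self.summary_ranks)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def run_stagewise(config: RunConfig) -> dict:
    """Run the full analysis; returns (and writes) the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    table = read_counts_table(config.table)
    metadata = read_metadata(config.metadata)
    taxonomy = read_taxonomy(config.taxonomy) if config.taxonomy else None
    tree = read_newick(config.tree) if config.tree else None

    known = [s for s in table.sample_ids if s in metadata.data.index]
    missing_meta = [s for s in table.sample_ids if s not in metadata.data.index]
    if missing_meta:
        raise KeyError(f"samples missing from metadata: {missing_meta}")
    table = table.select_samples(known)

    rar = rarefy(table, config.depth, seed=config.seed)
    rtab = rar.table
    manifest: dict = {
        "software": {"name": "assemblage", "version": assemblage.__version__},
        "config": config.to_dict(),
        "seed": config.seed,
        "rarefaction": {
            "depth": config.depth,
            "dropped_samples": list(rar.dropped_samples),
            "n_dropped_otus": len(rar.dropped_otus),
        },
        "stages": {},
        "skipped_stages": [],
        "exclusions": {},
    }

    # ---- alpha diversity ------------------------------------------------
    alpha = alpha_diversity_table(rtab, tree=tree)
    alpha = alpha.join(metadata.data, how="left")
    alpha.index.name = "sample_id"
    _write_tsv(alpha.reset_index(), out / "alpha.tsv")

    # ---- per-stage fits -------------------------------------------------
    ncm_rows = []
    venn_rows = []
    for stage in config.stages:
        larvae = [
            s
            for s in metadata.samples_where(habitat="larvae", stage=stage)
            if s in rtab.data.columns
        ]
        water = [
            s
            for s in metadata.samples_where(habitat="water", stage=stage)
            if s in rtab.data.columns
        ]
        if len(larvae) < MIN_LARVAE_PER_STAGE:
            log.warning(
                "stage %s skipped: %d larval samples (< %d)",
                stage,
                len(larvae),
                MIN_LARVAE_PER_STAGE,
            )
            manifest["skipped_stages"].append(stage)
            continue
        stage_info: dict = {"n_larvae": len(larvae), "n_water": len(water)}
        if water:
            venn = shared_otu_partition(rtab, larvae, water)
            venn_rows.append({"stage": stage, **venn})
        for mode in config.source_modes:
            if mode == "external" and len(water) < 2:
                log.warning("stage %s: no water source; external fit skipped", stage)
                continue
            fit = fit_ncm(
                rtab,
                larvae,
                source=(water if mode == "external" else "self"),
                band_method=config.band_method,
                n_boot=config.n_boot,
                alpha=config.alpha,
                seed=config.seed,
            )
            row = {"stage": stage, **fit.report_row()}
            ncm_rows.append(row)
            _write_tsv(
                pd.DataFrame([row]), out / f"ncm_{mode}_{stage}.tsv"
            )
            _write_tsv(
                fit.records_frame(taxonomy=taxonomy),
                out / f"ncm_otus_{mode}_{stage}.tsv",
            )
            if taxonomy is not None:
                for rank in config.summary_ranks:
                    summ = category_summary(fit, rtab, larvae, taxonomy, rank=rank)
                    _write_tsv(
                        summ.to_frame(),
                        out / f"categories_{mode}_{stage}_{rank}.tsv",
                    )
            stage_info[f"ncm_{mode}"] = {
                "m": fit.m,
                "r2": fit.r2,
                "aic_neutral": fit.aic_neutral,
                "aic_binomial": fit.aic_binomial,
                "n_otus_fit": fit.n_otus_fit,
                "category_counts": fit.category_counts(),
                "n_excluded_absent": fit.n_excluded_absent,
                "warnings": list(fit.warnings),
            }
        manifest["stages"][stage] = stage_info
    if ncm_rows:
        _write_tsv(pd.DataFrame(ncm_rows), out / "ncm_fits.tsv")
    if venn_rows:
        _write_tsv(pd.DataFrame(venn_rows), out / "venn.tsv")

    # ---- ordination and group separation --------------------------------
    metric_specs = [("bray_curtis", dict(metric="bray_curtis"))]
    if tree is not None:
        metric_specs.append(
            (
                "weighted_unifrac",
                dict(metric="weighted_unifrac", tree=tree, normalized=True),
            )
        )
    anosim_rows = []
    for metric_name, kw in metric_specs:
        for habitat in ("larvae", "water"):
            samples = [
                s
                for s in metadata.samples_where(habitat=habitat)
                if s in rtab.data.columns
            ]
            if len(samples) < 3:
                continue
            sub = rtab.select_samples(samples).drop_empty_otus()
            dm = distance_matrix(sub, **kw)
            res = pcoa(dm, k=2)
            coords = res.coordinates.copy()
            coords.index.name = "sample_id"
            path = out / f"pcoa_{metric_name}_{habitat}.tsv"
            with path.open("w") as fh:
                eig = ", ".join(FLOAT_FMT % v for v in res.eigenvalues[:5])
                fh.write(f"# eigenvalues (first 5): {eig}\n")
                coords.reset_index().to_csv(
                    fh, sep="\t", index=False, float_format=FLOAT_FMT
                )
            write_distance_matrix(dm, out / f"distance_{metric_name}_{habitat}.tsv")
            # stage-vs-stage within habitat
            stages_here = [
                metadata.data.loc[s, "stage"] for s in sub.sample_ids
            ]
            counts = pd.Series(stages_here).value_counts()
            if (counts >= 2).sum() >= 2:
                keep = [
                    s
                    for s, st in zip(sub.sample_ids, stages_here)
                    if counts[st] >= 2
                ]
                sub2 = sub.select_samples(keep)
                dm2 = distance_matrix(sub2, **kw)
                labels = [metadata.data.loc[s, "stage"] for s in keep]
                res2 = anosim(
                    dm2,
                    labels,
                    n_perm=config.anosim_permutations,
                    seed=config.seed + 11,
                )
                anosim_rows.append(
                    {
                        "comparison": f"stages_within_{habitat}",
                        "metric": metric_name,
                        "R": res2.R,
                        "p": res2.p,
                        "n_perm": res2.n_perm,
                    }
                )
        # larvae vs water per stage
        for stage in config.stages:
            larvae = [
                s
                for s in metadata.samples_where(habitat="larvae", stage=stage)
                if s in rtab.data.columns
            ]
            water = [
                s
                for s in metadata.samples_where(habitat="water", stage=stage)
                if s in rtab.data.columns
            ]
            if len(larvae) < 2 or len(water) < 2:
                continue
            sub = rtab.select_samples(larvae + water).drop_empty_otus()
            dm = distance_matrix(sub, **kw)
            labels = ["larvae"] * len(larvae) + ["water"] * len(water)
            res = anosim(
                dm, labels, n_perm=config.anosim_permutations, seed=config.seed + 13
            )
            anosim_rows.append(
                {
                    "comparison": f"larvae_vs_water_{stage}",
                    "metric": metric_name,
                    "R": res.R,
                    "p": res.p,
                    "n_perm": res.n_perm,
                }
            )
    if anosim_rows:
        _write_tsv(pd.DataFrame(anosim_rows), out / "anosim.tsv")

    # ---- time decay ------------------------------------------------------
    td_rows = []
    larvae_all = set(metadata.samples_where(habitat="larvae"))
    for metric in config.timedecay_metrics:
        try:
            series = pairwise_similarity_series(
                rtab,
                metadata,
                metric=metric,
                tree=tree,
                sample_filter=lambda s: s in larvae_all,
            )
            fit = fit_time_decay(series)
        except ValueError as exc:
            log.warning("time-decay (%s) skipped: %s", metric, exc)
            manifest["exclusions"][f"timedecay_{metric}"] = str(exc)
            continue
        td_rows.append(
            {
                "metric": metric,
                "w": fit.w,
                "log10_c": fit.log10_c,
                "r2": fit.r2,
                "p_value": fit.p_value,
                "n_pairs": fit.n_pairs,
                "n_excluded": fit.n_excluded,
            }
        )
        manifest["exclusions"][f"timedecay_{metric}_pairs"] = fit.n_excluded
    if td_rows:
        _write_tsv(pd.DataFrame(td_rows), out / "timedecay.tsv")

    with (out / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
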