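"""Data model and file I/O: OTU tables, taxonomy, sample metadata, trees.

The universal currency of the pipeline is the :class:`CommunityTable`, an
OTU x sample matrix of non-negative integer read counts. Everything
downstream (diversity, time-decay, neutral-model fitting) consumes either
a table or objects derived from one. Files are plain TSV/newick so that
every artifact in a run directory is diffable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "CommunityTable",
    "TaxonomyMap",
    "SampleMetadata",
    "TableFormatError",
    "RarefactionResult",
    "HABITATS",
    "STAGES",
    "TAXONOMIC_RANKS",
    "read_counts_table",
    "write_counts_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "write_metadata",
    "read_newick",
    "write_newick",
    "rarefy",
    "relative_abundance",
    "shared_otu_partition",
]

HABITATS = ("larvae", "water")
STAGES = ("nauplius", "zoeaI", "zoeaII", "zoeaIII", "mysis", "postlarvae")
TAXONOMIC_RANKS = ("domain", "phylum", "class", "order", "family", "genus")

OTU_TABLE_HEADER = "#OTU_ID"

# SILVA/greengenes-style rank prefixes: "D_0__Bacteria", "k__Bacteria", "p__..."
_RANK_PREFIX = re.compile(r"^(?:[A-Za-z]_?\d*_{2})")


class TableFormatError(ValueError):
    """Malformed input file (duplicate ids, negative or non-integer cells)."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise TableFormatError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class CommunityTable:
    """OTU x sample matrix of non-negative integer counts with id registries."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(list(df.index), "OTU")
        _check_unique(list(df.columns), "sample")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            # accept float frames only if they are exact integers
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                bad = np.argwhere(values != np.floor(values))
                r, c = (bad[0] if len(bad) else (0, 0))
                raise TableFormatError(
                    f"non-integer count at OTU {df.index[r]!r}, sample {df.columns[c]!r}"
                )
            df = df.astype(np.int64)
            object.__setattr__(self, "data", df)
            values = df.to_numpy()
        if values.size and values.min() < 0:
            r, c = np.argwhere(values < 0)[0]
            raise TableFormatError(
                f"negative count at OTU {df.index[r]!r}, sample {df.columns[c]!r}"
            )

    # -- registries ------------------------------------------------------
    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        """Counts as an (n_otus, n_samples) integer array (copy-free view)."""
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    # -- views -----------------------------------------------------------
    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def otu_sums(self) -> pd.Series:
        return self.data.sum(axis=1)

    def select_samples(self, sample_ids: Iterable[str]) -> "CommunityTable":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"unknown sample id(s): {missing}")
        return CommunityTable(self.data.loc[:, ids])

    def drop_empty_otus(self) -> "CommunityTable":
        keep = self.data.sum(axis=1) > 0
        return CommunityTable(self.data.loc[keep])

    def sample(self, sample_id: str) -> pd.Series:
        if sample_id not in self.data.columns:
            raise KeyError(f"unknown sample id: {sample_id!r}")
        return self.data[sample_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CommunityTable):
            return NotImplemented
        return self.data.equals(other.data)


def read_counts_table(path: str | Path) -> CommunityTable:
    """Read a TSV OTU table (rows OTUs, columns samples, integer counts)."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise TableFormatError(f"{path}: header must contain at least one sample id")
    sample_ids = header[1:]
    _check_unique(sample_ids, "sample")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    _check_unique(list(df.index), "OTU")
    try:
        numeric = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise TableFormatError(f"{path}: non-numeric cell ({exc})") from exc
    arr = numeric.to_numpy()
    frac = arr != np.floor(arr)
    if frac.any():
        r, c = np.argwhere(frac)[0]
        raise TableFormatError(
            f"{path}: non-integer count at row {numeric.index[r]!r}, "
            f"column {numeric.columns[c]!r}"
        )
    if arr.size and arr.min() < 0:
        r, c = np.argwhere(arr < 0)[0]
        raise TableFormatError(
            f"{path}: negative count at row {numeric.index[r]!r}, "
            f"column {numeric.columns[c]!r}"
        )
    return CommunityTable(numeric.astype(np.int64))


def write_counts_table(table: CommunityTable, path: str | Path) -> None:
    path = Path(path)
    df = table.data
    with path.open("w") as fh:
        fh.write(OTU_TABLE_HEADER + "\t" + "\t".join(df.columns) + "\n")
        for otu, row in zip(df.index, df.to_numpy()):
            fh.write(otu + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# taxonomy


@dataclass(frozen=True)
class TaxonomyMap:
    """Per-OTU ranked lineage from domain to genus.

    Missing ranks are explicit ``unclassified_<parent>`` placeholders so
    category summaries never silently merge unknowns.
    """

    lineages: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for otu, lin in self.lineages.items():
            if len(lin) != len(TAXONOMIC_RANKS):
                raise TableFormatError(
                    f"lineage for {otu!r} has {len(lin)} ranks, "
                    f"expected {len(TAXONOMIC_RANKS)}"
                )

    def name_at(self, otu_id: str, rank: str) -> str:
        if rank not in TAXONOMIC_RANKS:
            raise KeyError(
                f"unknown rank {rank!r}; valid ranks: {TAXONOMIC_RANKS}"
            )
        if otu_id not in self.lineages:
            raise KeyError(f"OTU {otu_id!r} absent from taxonomy")
        return self.lineages[otu_id][TAXONOMIC_RANKS.index(rank)]

    def lineage_string(self, otu_id: str) -> str:
        if otu_id not in self.lineages:
            raise KeyError(f"OTU {otu_id!r} absent from taxonomy")
        return ";".join(self.lineages[otu_id])

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self.lineages

    def __len__(self) -> int:
        return len(self.lineages)


def parse_lineage(lineage: str) -> tuple[str, ...]:
    """Parse a semicolon-delimited lineage, bare or rank-prefixed dialect."""
    names: list[str] = []
    for tok in lineage.split(";"):
        tok = _RANK_PREFIX.sub("", tok.strip())
        if tok and tok.lower() not in {"unclassified", "uncultured", "__"}:
            names.append(tok)
        else:
            names.append("")
    # truncate to canonical depth, pad with placeholders below
    names = names[: len(TAXONOMIC_RANKS)]
    out: list[str] = []
    parent = "root"
    for i in range(len(TAXONOMIC_RANKS)):
        name = names[i] if i < len(names) else ""
        if name:
            out.append(name)
            parent = name
        else:
            out.append(f"unclassified_{parent}")
    return tuple(out)


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a two-column TSV: OTU id, lineage string."""
    path = Path(path)
    lineages: dict[str, tuple[str, ...]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                parts = [parts[0], ""]
            otu, lineage = parts[0].strip(), parts[1]
            if otu in lineages:
                raise TableFormatError(
                    f"{path}:{lineno}: duplicate OTU identifier {otu!r}"
                )
            lineages[otu] = parse_lineage(lineage)
    return TaxonomyMap(lineages)


def write_taxonomy(taxonomy: TaxonomyMap, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for otu in taxonomy.lineages:
            fh.write(f"{otu}\t{taxonomy.lineage_string(otu)}\n")


# ---------------------------------------------------------------------------
# sample metadata


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample habitat / developmental stage / pond / time annotations."""

    data: pd.DataFrame  # index: sample_id; columns habitat, stage, pond, time_h

    REQUIRED = ("habitat", "stage", "pond", "time_h")

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(list(df.index), "sample")
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise TableFormatError(f"metadata missing column(s): {missing}")
        bad_h = sorted(set(df["habitat"]) - set(HABITATS))
        if bad_h:
            raise TableFormatError(f"unknown habitat value(s): {bad_h}")
        bad_s = sorted(set(df["stage"]) - set(STAGES))
        if bad_s:
            raise TableFormatError(f"unknown stage value(s): {bad_s}")
        if (df["time_h"].astype(float) < 0).any():
            raise TableFormatError("time_h must be >= 0")
        object.__setattr__(
            self, "data", df.assign(time_h=df["time_h"].astype(float))
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def require_samples(self, sample_ids: Iterable[str]) -> None:
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"sample(s) missing from metadata: {missing}")

    def samples_where(
        self,
        habitat: str | None = None,
        stage: str | None = None,
        pond: str | None = None,
    ) -> list[str]:
        df = self.data
        mask = pd.Series(True, index=df.index)
        if habitat is not None:
            mask &= df["habitat"] == habitat
        if stage is not None:
            mask &= df["stage"] == stage
        if pond is not None:
            mask &= df["pond"].astype(str) == str(pond)
        return list(df.index[mask])

    def time_h(self, sample_id: str) -> float:
        if sample_id not in self.data.index:
            raise KeyError(f"sample {sample_id!r} missing from metadata")
        return float(self.data.loc[sample_id, "time_h"])


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise TableFormatError(f"{path}: metadata must have a sample_id column")
    df = df.set_index("sample_id")
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    out = metadata.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# trees


def read_newick(path: str | Path, require_lengths: bool = True) -> TreeNode:
    """Read a single rooted newick tree with branch lengths."""
    path = Path(path)
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parse-error types
        raise TableFormatError(f"{path}: newick parse error: {exc}") from exc
    tips = [t.name for t in tree.tips()]
    _check_unique(tips, "tree tip")
    for node in tree.traverse(include_self=True):
        if node.is_root():
            if node.length is None:
                node.length = 0.0
            continue
        if node.length is None:
            if require_lengths:
                raise TableFormatError(
                    f"{path}: missing branch length on node "
                    f"{node.name or '<internal>'}"
                )
            node.length = 0.0
        if not np.isfinite(node.length) or node.length < 0:
            raise TableFormatError(
                f"{path}: invalid branch length {node.length!r} on node "
                f"{node.name or '<internal>'}"
            )
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# rarefaction


@dataclass(frozen=True)
class RarefactionResult:
    table: CommunityTable
    depth: int
    dropped_samples: tuple[str, ...]
    dropped_otus: tuple[str, ...]


def rarefy(
    table: CommunityTable, depth: int, seed: int | np.random.Generator
) -> RarefactionResult:
    """Subsample each sample to ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped and reported; OTUs
    left with zero counts everywhere are likewise dropped. The subsample is
    multivariate hypergeometric, so a sample whose total equals ``depth``
    passes through unchanged. Deterministic given the seed.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    sums = table.sample_sums()
    keep = [s for s in table.sample_ids if sums[s] >= depth]
    dropped = tuple(s for s in table.sample_ids if sums[s] < depth)
    if not keep:
        raise ValueError(f"no samples retained at depth {depth}")
    cols = {}
    for s in keep:
        col = table.data[s].to_numpy()
        if col.sum() == depth:
            cols[s] = col
        else:
            cols[s] = rng.multivariate_hypergeometric(col, depth)
    out = pd.DataFrame(cols, index=table.data.index)
    empty = out.index[out.sum(axis=1) == 0]
    out = out.drop(index=empty)
    return RarefactionResult(
        table=CommunityTable(out.astype(np.int64)),
        depth=depth,
        dropped_samples=dropped,
        dropped_otus=tuple(empty),
    )


def relative_abundance(table: CommunityTable) -> pd.DataFrame:
    """Per-sample relative abundances; every column sums to 1."""
    sums = table.sample_sums()
    zero = list(sums.index[sums == 0])
    if zero:
        raise ValueError(f"all-zero sample(s): {zero}")
    return table.data / sums


def shared_otu_partition(
    table: CommunityTable,
    samples_a: Iterable[str],
    samples_b: Iterable[str],
) -> dict[str, float]:
    """Venn partition of OTU occurrence between two disjoint sample sets."""
    a, b = list(samples_a), list(samples_b)
    if not a or not b:
        raise ValueError("both sample sets must be nonempty")
    overlap = set(a) & set(b)
    if overlap:
        raise ValueError(f"sample sets overlap: {sorted(overlap)}")
    occ_a = set(table.data.index[table.data[a].sum(axis=1) > 0])
    occ_b = set(table.data.index[table.data[b].sum(axis=1) > 0])
    shared = len(occ_a & occ_b)
    union = len(occ_a | occ_b)
    return {
        "unique_a": len(occ_a - occ_b),
        "unique_b": len(occ_b - occ_a),
        "shared": shared,
        "shared_fraction": shared / union if union else 0.0,
    }
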