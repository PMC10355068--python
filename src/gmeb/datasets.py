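"""Core data containers and file I/O for amplicon community data.

The universal pipeline input is a :class:`CommunityDataset`: a sample x OTU
integer count table, a 7-rank taxonomy map, per-well sample metadata, and an
optional rooted phylogenetic tree whose tips are OTU ids.

Conventions
-----------
* Samples are rows, taxa are columns, everywhere.  Readers transpose on
  detection (by matching metadata sample ids).
* Missing taxonomic ranks are stored as the literal sentinel
  ``"unclassified"``, never the empty string.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "RANKS",
    "UNCLASSIFIED",
    "OtuTable",
    "TaxonomyMap",
    "SampleMetadata",
    "CommunityDataset",
    "ValidationError",
    "read_community_data",
    "read_otu_table",
    "read_taxonomy",
    "read_metadata",
    "read_tree",
    "rarefy",
    "aggregate_rank",
    "relative_abundance",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
UNCLASSIFIED = "unclassified"

WELL_TYPES = frozenset({"newly_constructed", "reconstructed"})
WATER_TYPES = frozenset({"phreatic", "confined"})
GEO_ZONES = frozenset({"I", "II", "III", "IV", "V", "VI", "VII"})


class ValidationError(ValueError):
    """Raised when an input violates a dataset invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dupes = []
    for x in ids:
        if x in seen:
            dupes.append(x)
        seen[x] = 1
    if dupes:
        raise ValidationError(f"duplicate {what}: {sorted(set(dupes))}")


class OtuTable:
    """Sample x OTU matrix of non-negative integer counts.

    Parameters
    ----------
    counts : array-like or DataFrame, shape (n_samples, n_otus)
    sample_ids, otu_ids : sequences of unique strings (ignored when a
        DataFrame is given; its index/columns are used).
    """

    def __init__(self, counts, sample_ids=None, otu_ids=None):
        if isinstance(counts, pd.DataFrame):
            df = counts.copy()
        else:
            df = pd.DataFrame(np.asarray(counts), index=list(sample_ids), columns=list(otu_ids))
        if df.shape[0] < 1 or df.shape[1] < 1:
            raise ValidationError("count table needs at least 1 sample and 1 OTU")
        _check_unique(df.index, "sample ids")
        _check_unique(df.columns, "OTU ids")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(arr < 0):
            raise ValidationError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("counts must be integers")
        self.data = df.astype(np.int64)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.data.index.name = None
        self.data.columns.name = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def drop_empty_otus(self) -> "OtuTable":
        keep = self.data.columns[self.data.sum(axis=0) > 0]
        return OtuTable(self.data[keep])

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, OtuTable) and self.data.equals(other.data)

    def __repr__(self) -> str:
        return f"OtuTable({self.shape[0]} samples x {self.shape[1]} OTUs)"


class TaxonomyMap:
    """OTU id -> 7-rank lineage (kingdom..species), missing ranks unclassified."""

    def __init__(self, lineages: pd.DataFrame):
        df = lineages.copy()
        missing = [r for r in RANKS if r not in df.columns]
        for r in missing:
            df[r] = UNCLASSIFIED
        df = df[list(RANKS)]
        _check_unique(df.index, "taxonomy OTU ids")
        df = df.fillna(UNCLASSIFIED).replace("", UNCLASSIFIED)
        self.data = df.astype(str)
        self.data.index = self.data.index.astype(str)
        self.data.index.name = None

    @classmethod
    def from_lineage_strings(cls, mapping: dict[str, str]) -> "TaxonomyMap":
        """Build from semicolon-delimited lineage strings.

        SILVA-style rank prefixes (``d__``, ``p__`` ... ``s__``) are tolerated
        and stripped.
        """
        rows = {}
        for otu, lineage in mapping.items():
            parts = [p.strip() for p in str(lineage).split(";")]
            clean = []
            for p in parts:
                if len(p) >= 3 and p[1:3] == "__":
                    p = p[3:]
                clean.append(p if p else UNCLASSIFIED)
            clean = (clean + [UNCLASSIFIED] * 7)[:7]
            rows[otu] = clean
        return cls(pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS)))

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    def rank_of(self, otu_id: str, rank: str) -> str:
        return self.data.at[otu_id, rank]

    def to_tsv(self, path) -> None:
        lineage = self.data.apply(lambda r: ";".join(r), axis=1)
        pd.DataFrame({"lineage": lineage}).to_csv(path, sep="\t", index_label="otu_id")


class SampleMetadata:
    """Per-sample well metadata plus optional numeric environmental variables."""

    REQUIRED = ("latitude", "longitude", "well_depth", "well_type", "water_type", "geo_zone")

    def __init__(self, table: pd.DataFrame):
        df = table.copy()
        _check_unique(df.index, "metadata sample ids")
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing required columns: {missing}")
        df["latitude"] = df["latitude"].astype(float)
        df["longitude"] = df["longitude"].astype(float)
        df["well_depth"] = df["well_depth"].astype(float)
        if ((df["latitude"] < -90) | (df["latitude"] > 90)).any():
            raise ValidationError("latitude out of [-90, 90]")
        if ((df["longitude"] < -180) | (df["longitude"] > 180)).any():
            raise ValidationError("longitude out of [-180, 180]")
        if (df["well_depth"] <= 0).any():
            raise ValidationError("well_depth must be > 0")
        bad = set(df["well_type"]) - WELL_TYPES
        if bad:
            raise ValidationError(f"unknown well_type values: {sorted(bad)}")
        bad = set(df["water_type"]) - WATER_TYPES
        if bad:
            raise ValidationError(f"unknown water_type values: {sorted(bad)}")
        bad = set(df["geo_zone"].astype(str)) - GEO_ZONES
        if bad:
            raise ValidationError(f"unknown geo_zone values: {sorted(bad)}")
        self.data = df
        self.data.index = self.data.index.astype(str)
        self.data.index.name = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def env_columns(self) -> list[str]:
        return [
            c
            for c in self.data.columns
            if c not in self.REQUIRED and pd.api.types.is_numeric_dtype(self.data[c])
        ]

    def subset(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        return SampleMetadata(self.data.loc[list(sample_ids)])

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")


@dataclass
class CommunityDataset:
    """Count table + taxonomy + metadata + optional tree, cross-validated."""

    table: OtuTable
    taxonomy: TaxonomyMap
    metadata: SampleMetadata
    tree: TreeNode | None = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        missing_meta = set(self.table.sample_ids) - set(self.metadata.sample_ids)
        if missing_meta:
            raise ValidationError(f"samples absent from metadata: {sorted(missing_meta)}")
        missing_tax = set(self.table.otu_ids) - set(self.taxonomy.otu_ids)
        if missing_tax:
            raise ValidationError(f"OTUs absent from taxonomy: {sorted(missing_tax)}")
        if self.tree is not None:
            tips = {t.name for t in self.tree.tips()}
            if len(tips) != sum(1 for _ in self.tree.tips()):
                raise ValidationError("tree tip labels are not unique")
            missing_tips = set(self.table.otu_ids) - tips
            if missing_tips:
                raise ValidationError(f"OTUs absent from tree tips: {sorted(missing_tips)}")
            for node in self.tree.traverse(include_self=False):
                if node.length is None or not np.isfinite(node.length) or node.length < 0:
                    raise ValidationError("every tree branch needs a finite non-negative length")

    def subset_samples(self, sample_ids: Sequence[str]) -> "CommunityDataset":
        table = OtuTable(self.table.data.loc[list(sample_ids)])
        return CommunityDataset(table, self.taxonomy, self.metadata.subset(sample_ids), self.tree)

    def write(self, directory) -> dict[str, Path]:
        """Write the four standard files into *directory*; return the paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "table": directory / "otu_table.tsv",
            "taxonomy": directory / "taxonomy.tsv",
            "metadata": directory / "metadata.tsv",
        }
        self.table.to_tsv(paths["table"])
        self.taxonomy.to_tsv(paths["taxonomy"])
        self.metadata.to_tsv(paths["metadata"])
        if self.tree is not None:
            paths["tree"] = directory / "tree.nwk"
            self.tree.write(str(paths["tree"]))
        return paths


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_otu_table(path, metadata: SampleMetadata | None = None) -> OtuTable:
    """Read a TSV count table; orientation is auto-detected against metadata.

    The first column holds ids.  If the row ids do not match metadata sample
    ids but the column ids do, the table is transposed.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if metadata is not None:
        meta_ids = set(metadata.sample_ids)
        rows_match = len(set(df.index) & meta_ids) > 0
        cols_match = len(set(df.columns) & meta_ids) > 0
        if not rows_match and cols_match:
            df = df.T
    try:
        return OtuTable(df)
    except ValidationError:
        raise
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"could not parse count table {path}: {exc}") from exc


def read_taxonomy(path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if "lineage" in df.columns:
        return TaxonomyMap.from_lineage_strings(df["lineage"].to_dict())
    if df.shape[1] == 1:
        return TaxonomyMap.from_lineage_strings(df.iloc[:, 0].to_dict())
    return TaxonomyMap(df)


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def read_tree(path) -> TreeNode:
    tree = TreeNode.read(str(path))
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
    return tree


def read_community_data(table_path, taxonomy_path, metadata_path, tree_path=None) -> CommunityDataset:
    """Read and cross-validate the four standard files."""
    for p in (table_path, taxonomy_path, metadata_path) + ((tree_path,) if tree_path else ()):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    metadata = read_metadata(metadata_path)
    table = read_otu_table(table_path, metadata=metadata)
    taxonomy = read_taxonomy(taxonomy_path)
    tree = read_tree(tree_path) if tree_path else None
    return CommunityDataset(table, taxonomy, metadata, tree)


# ---------------------------------------------------------------------------
# table transforms
# ---------------------------------------------------------------------------

def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to exactly *depth* reads without replacement.

    Samples with fewer than *depth* reads are dropped (a warning lists them).
    Uses one multivariate-hypergeometric draw per sample; the same seed gives
    bit-identical output.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = totals.index[totals >= depth]
    dropped = sorted(set(table.sample_ids) - set(keep))
    if dropped:
        warnings.warn(
            f"rarefy: dropped {len(dropped)} sample(s) below depth {depth}: {dropped}",
            stacklevel=2,
        )
    if len(keep) == 0:
        raise ValidationError(f"all samples have fewer than {depth} reads")
    rows = []
    for sid in keep:
        counts = table.data.loc[sid].to_numpy()
        rows.append(rng.multivariate_hypergeometric(counts, depth))
    out = pd.DataFrame(np.vstack(rows), index=list(keep), columns=table.otu_ids)
    return OtuTable(out)


def aggregate_rank(table: OtuTable, taxonomy: TaxonomyMap, rank: str) -> OtuTable:
    """Sum OTU counts into taxa at *rank* (phylum..genus).

    OTUs unclassified at the rank pool into one ``unclassified_<rank>``
    column.  The grand total is preserved.
    """
    if rank not in RANKS[1:6]:
        raise ValueError(f"rank must be one of {RANKS[1:6]}, got {rank!r}")
    labels = []
    for otu in table.otu_ids:
        if otu in taxonomy.data.index:
            lab = taxonomy.rank_of(otu, rank)
        else:
            lab = UNCLASSIFIED
        labels.append(f"{UNCLASSIFIED}_{rank}" if lab == UNCLASSIFIED else lab)
    grouped = table.data.T.groupby(pd.Index(labels, name=rank)).sum().T
    return OtuTable(grouped)


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Row-normalized proportions; every row sums to 1 (within 1e-12)."""
    totals = table.sample_totals()
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValidationError(f"zero-total sample(s): {sorted(zero)}")
    return table.data.div(totals, axis=0)
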