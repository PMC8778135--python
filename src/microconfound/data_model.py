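"""Domain types and TSV/Newick I/O for microbiome feature-table analysis.

The central objects are a taxa-by-samples integer :class:`CountTable`, a
per-sample :class:`MetadataFrame` with declared variable types and a target
grouping variable (e.g. disease status), an optional :class:`TaxonomyTable`
of rank-delimited lineages, and a rooted phylogeny for UniFrac metrics.
All tabular I/O is plain UTF-8 TSV; trees are Newick.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import skbio
from skbio.stats.distance import DistanceMatrix  # noqa: F401  (re-exported)

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

NUMERIC = "numeric"
CATEGORICAL = "categorical"


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


# ---------------------------------------------------------------------------
# CountTable
# ---------------------------------------------------------------------------

@dataclass
class CountTable:
    """Taxa × samples matrix of non-negative integer read counts."""

    data: pd.DataFrame  # index = taxa, columns = samples, dtype int64

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon identifiers: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dups}")
        if df.shape[0] < 1 or df.shape[1] < 2:
            raise ValidationError(
                f"count table needs >=1 taxon and >=2 samples, got {df.shape}"
            )
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            as_float = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(as_float)):
                raise ValidationError("non-finite count values")
            if not np.allclose(as_float, np.round(as_float), atol=0, rtol=0):
                bad = np.argwhere(as_float != np.round(as_float))[0]
                raise ValidationError(
                    "fractional count at taxon "
                    f"{df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r}"
                )
            arr = as_float.astype(np.int64)
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at taxon {df.index[bad[0]]!r}, "
                f"sample {df.columns[bad[1]]!r}"
            )
        self.data = pd.DataFrame(arr, index=df.index.astype(str),
                                 columns=df.columns.astype(str))
        self.data.index.name = None
        self.data.columns.name = None

    @property
    def taxa_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def select_taxa(self, taxa: Sequence[str]) -> "CountTable":
        return CountTable(self.data.loc[list(taxa)])

    def select_samples(self, samples: Sequence[str]) -> "CountTable":
        return CountTable(self.data[list(samples)])


def read_count_table(path: str | Path | io.TextIOBase,
                     orientation: str = "taxa_rows") -> CountTable:
    """Read a TSV count table; ``orientation`` names what the rows are."""
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    num = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        try:
            num[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValidationError(
                f"non-numeric count at row {row!r}, column {col!r}"
            ) from exc
    if orientation == "samples_rows":
        num = num.T
    return CountTable(num)


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="taxon_id")


# ---------------------------------------------------------------------------
# MetadataFrame
# ---------------------------------------------------------------------------

@dataclass
class MetadataFrame:
    """Per-sample variables with declared types and a target grouping.

    Categorical level order is first appearance in the file, so design
    matrices are reproducible without hidden alphabetical reordering; the
    first level acts as the reference in dummy coding.
    """

    data: pd.DataFrame  # index = sample ids
    schema: dict[str, str]  # variable -> "numeric" | "categorical"
    target: str
    subgroup: str | None = None
    levels: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise ValidationError("duplicate sample identifiers in metadata")
        for var, kind in self.schema.items():
            if var not in df.columns:
                raise ValidationError(f"schema variable {var!r} not in metadata")
            if kind == NUMERIC:
                try:
                    df[var] = pd.to_numeric(df[var]).astype(float)
                except (ValueError, TypeError) as exc:
                    raise ValidationError(
                        f"numeric variable {var!r} has non-numeric entries"
                    ) from exc
            elif kind == CATEGORICAL:
                col = df[var].astype(str)
                if var not in self.levels:
                    self.levels[var] = list(dict.fromkeys(col))
                df[var] = col
            else:
                raise ValidationError(f"unknown type {kind!r} for {var!r}")
        if self.target not in df.columns:
            raise ValidationError(f"target variable {self.target!r} absent")
        if self.schema.get(self.target) != CATEGORICAL:
            raise ValidationError("target variable must be categorical")
        if df[self.target].nunique() < 2:
            raise ValidationError("target variable needs >=2 levels")
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def variables(self, exclude_target: bool = False) -> list[str]:
        out = [v for v in self.schema]
        if exclude_target:
            out = [v for v in out if v not in (self.target, self.subgroup)]
        return out

    def level_order(self, var: str) -> list[str]:
        return self.levels.get(var, list(dict.fromkeys(self.data[var].astype(str))))

    def aligned_to(self, sample_ids: Sequence[str]) -> "MetadataFrame":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")
        return MetadataFrame(self.data.loc[list(sample_ids)].copy(),
                             dict(self.schema), self.target, self.subgroup,
                             {k: list(v) for k, v in self.levels.items()})


def read_metadata(path: str | Path | io.TextIOBase,
                  schema: Mapping[str, str], target: str,
                  subgroup: str | None = None) -> MetadataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if target not in df.columns:
        raise ValidationError(
            f"target {target!r} not found in metadata header"
        )
    return MetadataFrame(df, dict(schema), target, subgroup)


def write_metadata(meta: MetadataFrame, path: str | Path) -> None:
    meta.data.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# TaxonomyTable
# ---------------------------------------------------------------------------

@dataclass
class TaxonomyTable:
    """taxon_id → ordered lineage strings (kingdom … species, <=7 ranks)."""

    data: pd.DataFrame  # index = taxon ids, columns ⊂ RANKS

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate taxon identifiers in taxonomy")
        unknown = [c for c in self.data.columns if c not in RANKS]
        if unknown:
            raise ValidationError(f"unknown ranks: {unknown}")
        self.data = self.data.fillna("").astype(str)

    @property
    def ranks(self) -> list[str]:
        return list(self.data.columns)

    def lineage(self, taxon_id: str, upto: str) -> tuple[str, ...]:
        if upto not in self.data.columns:
            raise ValidationError(f"unknown rank {upto!r}")
        cols = self.data.columns[: self.data.columns.get_loc(upto) + 1]
        return tuple(self.data.loc[taxon_id, cols])


def read_taxonomy(path: str | Path | io.TextIOBase) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return TaxonomyTable(df)


def write_taxonomy(tax: TaxonomyTable, path: str | Path) -> None:
    tax.data.to_csv(path, sep="\t", index_label="taxon_id")


# ---------------------------------------------------------------------------
# PhyloTree
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """Rooted phylogeny over (a superset of) the table's taxa.

    Wraps a scikit-bio ``TreeNode``. Unrooted inputs (trifurcating base)
    are midpoint-rooted, since UniFrac needs a root.
    """

    tree: skbio.TreeNode
    midpoint_rooted: bool = False

    def __post_init__(self) -> None:
        tips = [t.name for t in self.tree.tips()]
        seen: set[str] = set()
        for name in tips:
            if name in seen:
                raise ValidationError(f"duplicated tip label {name!r}")
            seen.add(name)
        for node in self.tree.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
        if len(self.tree.children) > 2:
            self.tree = self.tree.root_at_midpoint()
            self.midpoint_rooted = True

    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.tree.traverse(include_self=False))

    def sheared(self, names: Sequence[str]) -> skbio.TreeNode:
        """Copy of the tree pruned to ``names`` (internal unifurcations collapsed)."""
        return self.tree.shear(list(names))

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()


def read_tree(path: str | Path | io.StringIO) -> PhyloTree:
    try:
        tree = skbio.TreeNode.read(str(path) if isinstance(path, Path) else path,
                                   format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise ValidationError(f"unparseable Newick input: {exc}") from exc
    return PhyloTree(tree)


def write_tree(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")
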