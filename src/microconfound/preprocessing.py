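"""Taxonomic agglomeration, prevalence filtering, median-of-ratios normalization.

Size factors follow the DESeq2 median-of-ratios scheme: each sample's factor
is the median, over reference taxa, of the ratio between its count and the
taxon's geometric mean across samples. The ``poscounts`` variant computes
geometric means over positive entries only and takes the median over taxa
with a positive count in the sample — the recommended choice for sparse
microbiome tables, where an all-positive row rarely exists. Factors are
standardized to geometric mean 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .data_model import CountTable, TaxonomyTable, ValidationError


@dataclass
class SizeFactors:
    """Per-sample positive scaling constants, geometric mean 1."""

    factors: pd.Series  # index = sample ids

    def __post_init__(self) -> None:
        s = self.factors.astype(float)
        if not np.all(np.isfinite(s)) or (s <= 0).any():
            raise ValidationError("size factors must be positive and finite")
        self.factors = s

    @property
    def sample_ids(self) -> list[str]:
        return list(self.factors.index)

    def __getitem__(self, sample: str) -> float:
        return float(self.factors[sample])

    def log(self) -> pd.Series:
        return np.log(self.factors)


@dataclass
class NormalizedTable:
    """Counts divided by their sample's size factor."""

    data: pd.DataFrame

    @property
    def taxa_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


class FilterResult(NamedTuple):
    table: CountTable
    removed: list[str]


def agglomerate(table: CountTable, taxonomy: TaxonomyTable,
                rank: str) -> CountTable:
    """Sum taxa that share an identical lineage prefix up to ``rank``.

    Taxa with an empty value at ``rank`` are grouped per parent lineage
    under a sentinel ``unclassified-<parent>`` bin. Per-sample totals are
    conserved exactly.
    """
    if rank not in taxonomy.ranks:
        raise ValidationError(f"unknown rank {rank!r}; have {taxonomy.ranks}")
    missing = [t for t in table.taxa_ids if t not in taxonomy.data.index]
    if missing:
        raise ValidationError(f"taxa absent from taxonomy: {missing}")
    labels = {}
    for t in table.taxa_ids:
        lineage = taxonomy.lineage(t, rank)
        if lineage[-1] == "":
            parent = next((r for r in reversed(lineage[:-1]) if r), "root")
            labels[t] = ("|".join(lineage[:-1]), f"unclassified-{parent}")
        else:
            labels[t] = ("|".join(lineage[:-1]), lineage[-1])
    keys = pd.Series([f"{p}|{name}" if p else name for p, name in
                      (labels[t] for t in table.taxa_ids)],
                     index=table.taxa_ids)
    display = {f"{p}|{name}" if p else name: name for p, name in labels.values()}
    grouped = table.data.groupby(keys, sort=False).sum()
    # keep the short rank label unless two distinct lineages collide on it
    names = pd.Series([display[k] for k in grouped.index], index=grouped.index)
    grouped.index = [k if (names == n).sum() > 1 else n
                     for k, n in names.items()]
    return CountTable(grouped)


def prevalence_filter(table: CountTable,
                      min_prevalence: float = 0.10) -> FilterResult:
    """Keep taxa present (count > 0) in at least ``min_prevalence`` of samples.

    The boundary is inclusive: prevalence exactly equal to the threshold is
    kept.
    """
    if not 0 < min_prevalence <= 1:
        raise ValidationError("min_prevalence must be in (0, 1]")
    prev = (table.counts > 0).mean(axis=1)
    keep = prev >= min_prevalence - 1e-12
    removed = [t for t, k in zip(table.taxa_ids, keep) if not k]
    if not keep.any():
        raise ValidationError(
            "prevalence filter removed every taxon; review the threshold")
    return FilterResult(CountTable(table.data.loc[keep]), removed)


def size_factors(table: CountTable,
                 method: str = "poscounts") -> SizeFactors:
    """DESeq2-style size factors; ``median_of_ratios`` or sparse ``poscounts``."""
    counts = table.counts.astype(float)
    if (counts.sum(axis=0) == 0).any():
        raise ValidationError("every sample needs at least one positive count")
    if method == "median_of_ratios":
        all_pos = (counts > 0).all(axis=1)
        if not all_pos.any():
            raise ValidationError(
                "no taxon is positive in every sample; use method='poscounts'")
        ref = counts[all_pos]
        geo = np.exp(np.log(ref).mean(axis=1))
        ratios = ref / geo[:, None]
        s = np.median(ratios, axis=0)
    elif method == "poscounts":
        # geometric mean over positive entries but divided by the TOTAL
        # sample count (the DESeq2 "poscounts" convention), so sparse rows
        # get shrunken reference means
        with np.errstate(divide="ignore"):
            logc = np.where(counts > 0, np.log(counts), np.nan)
        geo = np.exp(np.nansum(logc, axis=1) / counts.shape[1])
        geo[~(counts > 0).any(axis=1)] = 0.0
        ratios = np.where((counts > 0) & (geo[:, None] > 0),
                          counts / np.where(geo > 0, geo, 1.0)[:, None], np.nan)
        s = np.nanmedian(ratios, axis=0)
    else:
        raise ValidationError(f"unknown size-factor method {method!r}")
    s = s / np.exp(np.mean(np.log(s)))  # standardize to geometric mean 1
    return SizeFactors(pd.Series(s, index=table.sample_ids))


def normalize(table: CountTable, s: SizeFactors) -> NormalizedTable:
    if set(table.sample_ids) != set(s.sample_ids):
        raise ValidationError("sample sets of table and size factors differ")
    f = s.factors[table.sample_ids]
    return NormalizedTable(table.data / f)
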