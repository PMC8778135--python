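"""Alpha-diversity estimators, a group test, and beta-diversity metrics.

Alpha metrics: bias-corrected Chao1 richness (on raw counts — singleton and
doubleton frequencies lose their meaning after fractional normalization),
Shannon entropy and the Gini–Simpson index (both on proportions, hence
scale-invariant). Groups are compared with a tie-corrected Kruskal–Wallis
test.

Beta metrics: Bray–Curtis, the normalized Canberra (divided by the number
of taxon pairs with a positive total, so it stays in [0,1]), and the
UniFrac family computed from the branch × taxon incidence of the supplied
rooted tree. Generalized UniFrac with exponent ``alpha`` interpolates
between emphasizing low- and high-abundance lineages; at alpha = 1 it
coincides with normalized weighted UniFrac.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DistanceMatrix, PhyloTree, ValidationError
from .preprocessing import NormalizedTable

ALPHA_METRICS = ("chao1", "shannon", "simpson")
BETA_METRICS = ("bray_curtis", "canberra", "unweighted_unifrac",
                "weighted_unifrac", "generalized_unifrac")


@dataclass
class AlphaResult:
    metric: str
    values: pd.Series  # per sample
    statistic: float   # Kruskal-Wallis H across groups
    p_value: float


def _check_counts(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValidationError("expected a 1-D count vector")
    if (x < 0).any():
        raise ValidationError("negative counts")
    if not (x > 0).any():
        raise ValidationError("all-zero count vector")
    return x


def chao1(counts) -> float:
    """Bias-corrected Chao1: S_obs + F1(F1-1) / (2(F2+1))."""
    x = _check_counts(counts)
    s_obs = float((x > 0).sum())
    f1 = float((x == 1).sum())
    f2 = float((x == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))


def shannon(counts, base: float | None = None) -> float:
    """Shannon entropy -sum p log p; natural log unless ``base`` given."""
    x = _check_counts(counts)
    p = x[x > 0] / x.sum()
    h = float(-(p * np.log(p)).sum())
    return h / np.log(base) if base else h


def simpson(counts) -> float:
    """Gini-Simpson index 1 - sum p^2."""
    x = _check_counts(counts)
    p = x / x.sum()
    return float(1.0 - (p ** 2).sum())


def alpha_group_test(values: pd.Series, groups: pd.Series) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) across the group labels."""
    groups = groups.loc[values.index]
    labels = groups.unique()
    if len(labels) < 2:
        raise ValidationError("need at least 2 groups")
    samples = [values[groups == g].to_numpy() for g in labels]
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):  # all ties: no evidence against the null
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def alpha_diversity(counts_df: pd.DataFrame, groups: pd.Series,
                    metrics=ALPHA_METRICS) -> dict[str, AlphaResult]:
    """Per-sample alpha values and the group test for each metric.

    ``counts_df`` is taxa × samples (raw counts: Chao1 requires them;
    Shannon/Simpson are scale-invariant so raw vs normalized is immaterial).
    """
    funcs = {"chao1": chao1, "shannon": shannon, "simpson": simpson}
    out = {}
    for m in metrics:
        vals = counts_df.apply(funcs[m], axis=0)
        h, p = alpha_group_test(vals, groups)
        out[m] = AlphaResult(m, vals, h, p)
    return out


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def _pairwise(x: np.ndarray, fn) -> np.ndarray:
    n = x.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fn(x[:, i], x[:, j])
    return d


def _bray_curtis(a, b) -> float:
    tot = (a + b).sum()
    return float(np.abs(a - b).sum() / tot) if tot > 0 else 0.0


def _canberra(a, b) -> float:
    nz = (a + b) > 0
    if not nz.any():
        return 0.0
    return float((np.abs(a - b)[nz] / (a + b)[nz]).sum() / nz.sum())


def branch_matrix(tree: PhyloTree, taxa: list[str]
                  ) -> tuple[np.ndarray, np.ndarray]:
    """(branch lengths, branch × taxon incidence) of the tree sheared to taxa."""
    tip_set = set(tree.tip_names)
    missing = [t for t in taxa if t not in tip_set]
    if missing:
        raise ValidationError(f"taxa absent from tree: {missing}")
    sub = tree.sheared(taxa)
    col = {t: i for i, t in enumerate(taxa)}
    lengths, rows = [], []
    for node in sub.traverse(include_self=False):
        inc = np.zeros(len(taxa))
        for tip in node.tips(include_self=True):
            inc[col[tip.name]] = 1.0
        lengths.append(float(node.length or 0.0))
        rows.append(inc)
    return np.asarray(lengths), np.asarray(rows)


def _unifrac_matrix(x: np.ndarray, lengths: np.ndarray, inc: np.ndarray,
                    variant: str, alpha: float) -> np.ndarray:
    totals = x.sum(axis=0)
    if (totals == 0).any():
        raise ValidationError("sample with zero total abundance")
    props = x / totals  # taxon proportions per sample
    branch = inc @ props  # branch-wise descendant proportion per sample
    present = inc @ (x > 0) > 0
    n = x.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = branch[:, i], branch[:, j]
            if variant == "unweighted":
                ai, bj = present[:, i], present[:, j]
                union = lengths[ai | bj].sum()
                uniq = lengths[ai ^ bj].sum()
                d[i, j] = uniq / union if union > 0 else 0.0
            elif variant == "weighted":
                denom = (lengths * (a + b)).sum()
                d[i, j] = (lengths * np.abs(a - b)).sum() / denom if denom else 0.0
            elif variant == "weighted_raw":
                d[i, j] = (lengths * np.abs(a - b)).sum()
            else:  # generalized
                s = a + b
                m = s > 0
                w = lengths[m] * s[m] ** alpha
                d[i, j] = ((w * np.abs(a - b)[m] / s[m]).sum() / w.sum()
                           if w.sum() > 0 else 0.0)
            d[j, i] = d[i, j]
    return d


def beta_distance(table: NormalizedTable, metric: str,
                  tree: PhyloTree | None = None,
                  alpha: float = 0.5) -> DistanceMatrix:
    """Sample × sample dissimilarity matrix for one beta metric."""
    if metric not in BETA_METRICS and metric != "weighted_unifrac_raw":
        raise ValidationError(f"unknown beta metric {metric!r}")
    x = table.values.astype(float)
    if metric == "bray_curtis":
        d = _pairwise(x, _bray_curtis)
    elif metric == "canberra":
        d = _pairwise(x, _canberra)
    else:
        if tree is None:
            raise ValidationError(f"metric {metric!r} requires a tree")
        if not 0.0 <= alpha <= 1.0:
            raise ValidationError("alpha must be in [0, 1]")
        lengths, inc = branch_matrix(tree, table.taxa_ids)
        variant = {"unweighted_unifrac": "unweighted",
                   "weighted_unifrac": "weighted",
                   "weighted_unifrac_raw": "weighted_raw",
                   "generalized_unifrac": "generalized"}[metric]
        d = _unifrac_matrix(x, lengths, inc, variant, alpha)
    return DistanceMatrix(d, ids=table.sample_ids)
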