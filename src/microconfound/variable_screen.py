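"""Confounder screening and PERMANOVA-based covariate selection.

Two complementary notions of "biasing variable" are screened:

* **Confounders** — variables unbalanced across the target groups. Numeric
  variables are tested with Kruskal–Wallis, categorical ones with Fisher's
  exact test on the group × level contingency table; p < 0.05 flags a
  potential confounder.
* **Covariates** — variables that explain beta-diversity variance. Each
  candidate's *marginal* effect (its extra sum of squares given all other
  terms) is tested by permutational multivariate ANOVA on the distance
  matrix; per metric, backward elimination repeatedly drops the least
  significant non-target term until all survivors have p < alpha, and the
  covariate set is the union of survivors across metrics.

The marginal PERMANOVA works on the Gower-centered matrix
G = -1/2 · J D∘D J: for term t, SS_t = SS(full) − SS(all terms but t),
pseudo-F_t = (SS_t/df_t)/(SS_res/df_res), and the permutation p-value uses
whole-row/column permutations of D with the add-one estimator
(1 + #{F* ≥ F}) / (1 + n_perm), so it is never exactly zero.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .data_model import (
    CATEGORICAL, NUMERIC, DistanceMatrix, MetadataFrame, ValidationError,
)

# 2xk Fisher tables with more enumerable states than this use Monte Carlo
FISHER_ENUM_LIMIT = 2_000_000


# ---------------------------------------------------------------------------
# design matrices (shared with the GLM stage)
# ---------------------------------------------------------------------------

def design_columns(meta: MetadataFrame, terms: list[str]
                   ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Dummy-coded columns (no intercept) and the term → columns map.

    Categorical terms are coded against their first recorded level (first
    appearance in the source file), numeric terms enter as-is.
    """
    cols = {}
    term_map: dict[str, list[str]] = {}
    for term in terms:
        if term not in meta.schema:
            raise ValidationError(f"unknown model term {term!r}")
        if meta.schema[term] == NUMERIC:
            cols[term] = meta.data[term].astype(float)
            term_map[term] = [term]
        else:
            levels = meta.level_order(term)
            if len(levels) < 2:
                raise ValidationError(f"term {term!r} is constant")
            names = []
            for lev in levels[1:]:
                name = f"{term}[{lev}]"
                cols[name] = (meta.data[term] == lev).astype(float)
                names.append(name)
            term_map[term] = names
    return pd.DataFrame(cols, index=meta.data.index), term_map


# ---------------------------------------------------------------------------
# unbalance screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenReport:
    """Per-variable test outcome; ``confounder`` flags p < alpha."""

    table: pd.DataFrame  # index var; columns test, statistic, p_value, confounder
    alpha: float = 0.05

    @property
    def confounders(self) -> list[str]:
        flagged = self.table[self.table["confounder"].fillna(False)]
        return list(flagged.index)


def fisher_exact_2xk(table: np.ndarray, rng: np.random.Generator | None = None,
                     n_mc: int = 200_000) -> tuple[float, str]:
    """Two-sided Fisher's exact test for a 2 × k table.

    Exact enumeration of all tables with the observed margins (two-sided:
    total probability of tables no more probable than the observed one);
    above :data:`FISHER_ENUM_LIMIT` enumerable states, a seeded Monte-Carlo
    estimate over random tables with fixed margins is used instead and the
    second return value says so.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape[0] != 2:
        raise ValidationError("fisher_exact_2xk expects a 2-row table")
    col = t.sum(axis=0)
    row1 = int(t[0].sum())
    n = int(t.sum())

    def log_prob(a: np.ndarray) -> float:
        # P(table) = prod_c C(col_c, a_c) / C(n, row1)
        lp = -(gammaln(n + 1) - gammaln(row1 + 1) - gammaln(n - row1 + 1))
        for c, ac in zip(col, a):
            lp += gammaln(c + 1) - gammaln(ac + 1) - gammaln(c - ac + 1)
        return float(lp)

    obs_lp = log_prob(t[0])
    n_states = int(np.prod(col[:-1] + 1))
    if n_states <= FISHER_ENUM_LIMIT:
        p = 0.0
        ranges = [range(int(c) + 1) for c in col[:-1]]
        for head in itertools.product(*ranges):
            last = row1 - sum(head)
            if not 0 <= last <= col[-1]:
                continue
            lp = log_prob(np.array(list(head) + [last]))
            if lp <= obs_lp + 1e-9:
                p += np.exp(lp)
        return min(1.0, p), "exact"
    # margin-conditional Monte Carlo: permute row labels, keep margins exact
    rng = rng or np.random.default_rng(0)
    labels = np.repeat(np.arange(len(col)), col)
    hits = 0
    for _ in range(n_mc):
        rng.shuffle(labels)
        a = np.bincount(labels[:row1], minlength=len(col))
        if log_prob(a) <= obs_lp + 1e-9:
            hits += 1
    return (hits + 1) / (n_mc + 1), "monte_carlo"


def unbalance_screen(meta: MetadataFrame, target: str | None = None,
                     variables: list[str] | None = None,
                     alpha: float = 0.05,
                     seed: int = 0) -> ScreenReport:
    """Kruskal–Wallis (numeric) / Fisher's exact (categorical) balance screen."""
    target = target or meta.target
    if meta.schema.get(target) != CATEGORICAL:
        raise ValidationError("target must be categorical")
    group = meta.data[target]
    if group.nunique() < 2:
        raise ValidationError("target needs >=2 levels")
    if variables is None:
        variables = [v for v in meta.schema
                     if v not in (target, meta.target, meta.subgroup)]
    rng = np.random.default_rng(seed)
    rows = []
    for var in variables:
        col = meta.data[var]
        if col.nunique() < 2:
            warnings.warn(f"variable {var!r} is constant; skipped")
            rows.append((var, "skipped", np.nan, np.nan, None))
            continue
        if meta.schema[var] == NUMERIC:
            samples = [col[group == g].to_numpy(dtype=float)
                       for g in group.unique()]
            stat, p = stats.kruskal(*samples)
            rows.append((var, "kruskal_wallis", float(stat), float(p),
                         bool(p < alpha)))
        else:
            ct = pd.crosstab(col, group).to_numpy()
            if ct.shape[0] == 2:
                p, how = fisher_exact_2xk(ct, rng)
            elif ct.shape[1] == 2:
                p, how = fisher_exact_2xk(ct.T, rng)
            elif ct.shape == (2, 2):
                _, p = stats.fisher_exact(ct)
                how = "exact"
            else:
                raise ValidationError(
                    f"variable {var!r}: only 2 x k contingency tables supported")
            rows.append((var, f"fisher_{how}", np.nan, float(p),
                         bool(p < alpha)))
    table = pd.DataFrame(rows, columns=["variable", "test", "statistic",
                                        "p_value", "confounder"]
                         ).set_index("variable")
    return ScreenReport(table, alpha)


# ---------------------------------------------------------------------------
# marginal PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    terms: pd.DataFrame  # index term; columns ss, df, pseudo_f, p_value
    residual_ss: float
    residual_df: int
    total_ss: float
    n_permutations: int
    seed: int

    def p(self, term: str) -> float:
        return float(self.terms.loc[term, "p_value"])


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    n = d.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return j @ a @ j


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    keep = diag > max(x.shape) * np.finfo(float).eps * (diag.max() or 1.0)
    q = q[:, keep]
    return q @ q.T, int(keep.sum())


def permanova_marginal(d: DistanceMatrix, meta: MetadataFrame,
                       terms: list[str], n_perm: int = 9999,
                       seed: int = 0) -> PermanovaResult:
    """Marginal-effects (type-III) PERMANOVA with whole-row permutations."""
    meta = meta.aligned_to(list(d.ids))
    x_df, term_map = design_columns(meta, terms)
    n = len(d.ids)
    cols_total = 1 + x_df.shape[1]
    if n < cols_total + 2:
        raise ValidationError("too few samples for the requested model")
    intercept = np.ones((n, 1))
    x_full = np.hstack([intercept, x_df.to_numpy()])
    h_full, rank_full = _hat(x_full)
    if rank_full < cols_total:
        for t1, t2 in itertools.combinations(terms, 2):
            both = np.hstack([intercept,
                              x_df[term_map[t1] + term_map[t2]].to_numpy()])
            _, r_both = _hat(both)
            if r_both < 1 + len(term_map[t1]) + len(term_map[t2]):
                raise ValidationError(
                    f"design is rank-deficient: terms {t1!r} and {t2!r} are aliased")
        raise ValidationError("design matrix is rank-deficient")
    g = _gower_center(np.asarray(d.data, dtype=float))
    total_ss = float(np.trace(g))
    ss_full = float(np.sum(h_full * g))  # = tr(H G), H symmetric
    ss_res = total_ss - ss_full
    df_res = n - rank_full

    h_reduced, df_terms = {}, {}
    for t in terms:
        other = [c for tt in terms if tt != t for c in term_map[tt]]
        x_red = np.hstack([intercept, x_df[other].to_numpy()])
        h_red, rank_red = _hat(x_red)
        h_reduced[t] = h_red
        df_terms[t] = rank_full - rank_red

    obs_ss = {t: ss_full - float(np.sum(h_reduced[t] * g)) for t in terms}
    obs_f = {t: (obs_ss[t] / df_terms[t]) / (ss_res / df_res) for t in terms}

    rng = np.random.default_rng(seed)
    exceed = {t: 0 for t in terms}
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_full_p = float(np.sum(h_full * gp))
        ss_res_p = total_ss - ss_full_p
        for t in terms:
            ss_t = ss_full_p - float(np.sum(h_reduced[t] * gp))
            f_t = (ss_t / df_terms[t]) / (ss_res_p / df_res)
            # tolerance so relabelings tied with the observed statistic
            # are counted despite summation-order rounding
            if f_t >= obs_f[t] - 1e-8 * max(1.0, abs(obs_f[t])):
                exceed[t] += 1
    table = pd.DataFrame(
        {"ss": [obs_ss[t] for t in terms],
         "df": [df_terms[t] for t in terms],
         "pseudo_f": [obs_f[t] for t in terms],
         "p_value": [(exceed[t] + 1) / (n_perm + 1) for t in terms]},
        index=pd.Index(terms, name="term"))
    return PermanovaResult(table, ss_res, df_res, total_ss, n_perm, seed)


# ---------------------------------------------------------------------------
# backward elimination
# ---------------------------------------------------------------------------

@dataclass
class CovariateSet:
    selected: dict[str, list[str]]       # metric -> surviving non-target terms
    union: list[str]
    trace: pd.DataFrame                  # metric, step, dropped term, p at removal
    final_results: dict[str, PermanovaResult] = field(default_factory=dict)


def stepwise_covariate_selection(distances: dict[str, DistanceMatrix],
                                 meta: MetadataFrame,
                                 candidates: list[str],
                                 target: str | None = None,
                                 alpha: float = 0.05,
                                 n_perm: int = 999,
                                 seed: int = 0) -> CovariateSet:
    """Per-metric backward elimination; covariates = union of survivors.

    The target term is never eliminated. Ties in the largest p-value drop
    the term appearing later in ``candidates`` order (deterministic).
    """
    target = target or meta.target
    if target in candidates:
        raise ValidationError("candidates must exclude the target variable")
    if not distances:
        raise ValidationError("need at least one distance matrix")
    order = {v: i for i, v in enumerate(candidates)}
    seeds = iter(np.random.SeedSequence(seed).generate_state(
        len(distances) * (len(candidates) + 1) * 2) % (2 ** 31))
    selected: dict[str, list[str]] = {}
    final: dict[str, PermanovaResult] = {}
    trace_rows = []
    for metric, d in distances.items():
        terms = [target] + list(candidates)
        step = 0
        while True:
            res = permanova_marginal(d, meta, terms, n_perm=n_perm,
                                     seed=int(next(seeds)))
            nontarget = [t for t in terms if t != target]
            if not nontarget:
                break
            pvals = res.terms.loc[nontarget, "p_value"]
            worst_p = pvals.max()
            if worst_p < alpha:
                break
            ties = [t for t in nontarget if pvals[t] == worst_p]
            drop = max(ties, key=lambda t: order[t])
            trace_rows.append((metric, step, drop, float(worst_p)))
            terms.remove(drop)
            step += 1
        selected[metric] = [t for t in terms if t != target]
        final[metric] = res
    union = [v for v in candidates
             if any(v in sel for sel in selected.values())]
    trace = pd.DataFrame(trace_rows,
                         columns=["metric", "step", "dropped", "p_at_removal"])
    return CovariateSet(selected, union, trace, final)


def covariate_matrix(covset: CovariateSet, target: str) -> pd.DataFrame:
    """Term × metric p-value matrix of the final per-metric models."""
    metrics = list(covset.final_results)
    terms = [target] + sorted({t for sel in covset.selected.values()
                               for t in sel})
    out = pd.DataFrame(index=terms, columns=metrics, dtype=float)
    for m, res in covset.final_results.items():
        for t in res.terms.index:
            out.loc[t, m] = res.p(t)
    return out
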