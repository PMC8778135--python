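"""Per-taxon GLM differential abundance under two competing models.

For every taxon the analysis fits count GLMs with a log link and a log
size-factor offset, under two designs:

* **target-only model** ("IBD model"): full = target, reduced = intercept;
* **adjusted model** ("IBDCC model"): full = target + covariates +
  confounders, reduced = the same without the target.

Four count families compete — Poisson, negative binomial (NB2),
zero-inflated NB (intercept-only inflation) and a hurdle model (binomial
zero part + zero-truncated NB positive part, both on the count design).
The family with the lowest BIC of the *full* fit is selected and reused
for the reduced fit, so the likelihood-ratio test compares nested models
within one family; BIC = −2·loglik + #params·log(n). LRT p-values are
Benjamini–Hochberg adjusted across taxa within each model run.

Taxa significant under exactly one of the two models are the
"non-overlapping" taxa; for those, attribution asks which single variable
explains the discrepancy by (1) adding each variable alone to the
target-only model and (2) removing each variable alone from the adjusted
model, flagging a variable when adding it destroys the target's
significance and removing it restores it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.discrete.count_model import ZeroInflatedNegativeBinomialP
from statsmodels.discrete.discrete_model import NegativeBinomial, Poisson
from statsmodels.discrete.truncated_model import TruncatedLFNegativeBinomialP

from .data_model import CountTable, MetadataFrame, ValidationError
from .preprocessing import SizeFactors, size_factors as compute_size_factors
from .variable_screen import design_columns

FAMILIES = ("poisson", "nb", "zinb", "hurdle")
_FAMILY_RANK = {f: i for i, f in enumerate(FAMILIES)}  # tie-break: simplest wins


@dataclass
class DesignSpec:
    """Model terms for one taxon regression; renders an R-style formula."""

    target: str | None
    variables: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        deduped = []
        for v in self.variables:
            if v == self.target:
                raise ValidationError("target duplicated among variables")
            if v not in seen:
                seen.add(v)
                deduped.append(v)
        self.variables = deduped

    @property
    def terms(self) -> list[str]:
        return ([self.target] if self.target else []) + self.variables

    def reduced(self) -> "DesignSpec":
        return DesignSpec(None, list(self.variables))

    def formula(self) -> str:
        rhs = " + ".join(self.terms) if self.terms else "1"
        return f"Taxon ~ {rhs}"

    def matrix(self, meta: MetadataFrame) -> pd.DataFrame:
        x = pd.DataFrame({"Intercept": np.ones(len(meta.data))},
                         index=meta.data.index)
        if self.terms:
            cols, _ = design_columns(meta, self.terms)
            x = pd.concat([x, cols], axis=1)
        return x


@dataclass
class GlmFit:
    family: str
    params: pd.Series
    bse: pd.Series
    loglik: float
    n_params: int
    n_obs: int
    converged: bool
    flags: list[str] = field(default_factory=list)

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.n_obs)


def _failed(family: str, n_obs: int, reason: str) -> GlmFit:
    return GlmFit(family, pd.Series(dtype=float), pd.Series(dtype=float),
                  -np.inf, 0, n_obs, False, [reason])


def fit_taxon_glm(y: np.ndarray, design: pd.DataFrame,
                  offset: np.ndarray, family: str) -> GlmFit:
    """Maximum-likelihood fit of one count family with log link and offset.

    Numerical failures are reported through the ``converged`` flag, never
    raised, so a failed family simply drops out of BIC selection.
    """
    y = np.asarray(y)
    if (y < 0).any() or not np.issubdtype(y.dtype, np.integer):
        raise ValidationError("response must be non-negative integer counts")
    if not (y > 0).any():
        raise ValidationError("all-zero response; taxon should be filtered")
    if family not in FAMILIES:
        raise ValidationError(f"unknown family {family!r}")
    x = design.to_numpy(dtype=float)
    names = list(design.columns)
    n = len(y)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        return _failed(family, n, "rank-deficient design")
    try:
        with warnings.catch_warnings(), np.errstate(all="ignore"):
            warnings.simplefilter("ignore")
            return _fit(y, x, names, offset, family, n)
    except Exception as exc:  # statsmodels raises many optimizer errors
        return _failed(family, n, f"fit error: {exc}")


def _converged(res) -> bool:
    return bool(res.mle_retvals.get("converged", False))


def _fit(y, x, names, offset, family, n) -> GlmFit:
    if family == "poisson":
        res = Poisson(y, x, offset=offset).fit(disp=0, maxiter=200)
        return GlmFit("poisson", pd.Series(res.params, index=names),
                      pd.Series(res.bse, index=names), float(res.llf),
                      len(res.params), n, _converged(res))
    if family == "nb":
        start = None
        try:
            pre = Poisson(y, x, offset=offset).fit(disp=0, maxiter=200)
            start = np.r_[pre.params, 0.5]
        except Exception:
            pass
        res = NegativeBinomial(y, x, offset=offset).fit(
            disp=0, maxiter=500, start_params=start)
        idx = names + ["alpha"]
        return GlmFit("nb", pd.Series(res.params, index=idx),
                      pd.Series(res.bse, index=idx), float(res.llf),
                      len(res.params), n, _converged(res))
    if family == "zinb":
        res = ZeroInflatedNegativeBinomialP(
            y, x, exog_infl=np.ones((n, 1)), offset=offset).fit(
            disp=0, maxiter=500)
        idx = ["inflate_Intercept"] + names + ["alpha"]
        ok = _converged(res) and np.isfinite(res.llf)
        return GlmFit("zinb", pd.Series(res.params, index=idx),
                      pd.Series(res.bse, index=idx), float(res.llf),
                      len(res.params), n, ok)
    # hurdle: binomial zero part + zero-truncated NB on the positives;
    # the parts are orthogonal so log-likelihoods add
    pos = y > 0
    flags: list[str] = []
    if pos.all():
        return _failed("hurdle", n, "no zeros: hurdle zero part degenerate")
    if pos.sum() <= x.shape[1] + 1:
        return _failed("hurdle", n, "too few positive counts")
    zero_res = sm.GLM(pos.astype(float), x,
                      family=sm.families.Binomial()).fit()
    if np.abs(zero_res.params).max() > 15:  # quasi-separation in zero part
        flags.append("separation in zero part")
    trunc = TruncatedLFNegativeBinomialP(
        y[pos], x[pos], offset=offset[pos], truncation=0).fit(
        disp=0, maxiter=500)
    params = pd.concat([
        pd.Series(zero_res.params, index=[f"zero_{c}" for c in names]),
        pd.Series(trunc.params, index=names + ["alpha"])])
    bse = pd.concat([
        pd.Series(zero_res.bse, index=[f"zero_{c}" for c in names]),
        pd.Series(trunc.bse, index=names + ["alpha"])])
    llf = float(zero_res.llf + trunc.llf)
    ok = _converged(trunc) and np.isfinite(llf) and "separation in zero part" not in flags
    return GlmFit("hurdle", params, bse, llf,
                  len(zero_res.params) + len(trunc.params), n, ok, flags)


def select_distribution(y: np.ndarray, design: pd.DataFrame,
                        offset: np.ndarray,
                        families=FAMILIES) -> tuple[str | None, dict[str, GlmFit]]:
    """Fit every family on the full design; return the lowest-BIC winner.

    Ties within 1e-9 go to the simplest family (poisson < nb < zinb <
    hurdle). Returns (None, fits) when nothing converges.
    """
    fits = {f: fit_taxon_glm(y, design, offset, f) for f in families}
    usable = {f: fit for f, fit in fits.items()
              if fit.converged and np.isfinite(fit.loglik)}
    if not usable:
        return None, fits
    best_bic = min(fit.bic for fit in usable.values())
    tied = [f for f, fit in usable.items() if fit.bic <= best_bic + 1e-9]
    best = min(tied, key=lambda f: _FAMILY_RANK[f])
    return best, fits


def lrt_compare(full: GlmFit, reduced: GlmFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fits: 2Δloglik (clipped at 0) ~ χ²."""
    if full.family != reduced.family:
        raise ValidationError("LRT requires the same family")
    if full.n_obs != reduced.n_obs:
        raise ValidationError("LRT requires the same data")
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValidationError("models are not nested (reduced has more params)")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    if df == 0:
        return stat, 0, 1.0
    return stat, df, float(stats.chi2.sf(stat, df))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValidationError("expected a 1-D p-value vector")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# model suites
# ---------------------------------------------------------------------------

@dataclass
class SuiteResult:
    """Per-taxon test results of one model run (IBD or IBDCC)."""

    mode: str
    results: pd.DataFrame  # index taxon; family, lrt, df, p_value, adj_p, significant
    skipped: dict[str, str] = field(default_factory=dict)
    alpha: float = 0.05

    @property
    def significant_taxa(self) -> list[str]:
        return list(self.results.index[self.results["significant"]])


def _test_one_taxon(y, x_full, x_red, offset, families
                    ) -> tuple[str, float, int, float] | str:
    """Select family on the full design, LRT against the reduced design.

    Falls back to the next-best converged family when the winner cannot be
    refit on the reduced design. Returns a reason string on total failure.
    """
    best, fits = select_distribution(y, x_full, offset, families)
    if best is None:
        return "no family converged on the full design"
    usable = sorted((f for f, fit in fits.items()
                     if fit.converged and np.isfinite(fit.loglik)),
                    key=lambda f: (fits[f].bic, _FAMILY_RANK[f]))
    for fam in usable:
        reduced = fit_taxon_glm(y, x_red, offset, fam)
        if reduced.converged and np.isfinite(reduced.loglik):
            stat, df, p = lrt_compare(fits[fam], reduced)
            return fam, stat, df, p
    return "no family converged on both designs"


def run_model_suite(table: CountTable, meta: MetadataFrame,
                    target: str | None = None,
                    covariates: list[str] | None = None,
                    confounders: list[str] | None = None,
                    s: SizeFactors | None = None,
                    mode: str = "IBDCC",
                    alpha: float = 0.05,
                    families=FAMILIES) -> SuiteResult:
    """Full-vs-reduced LRT per taxon with BH correction across taxa.

    ``mode="IBDCC"``: full = target + covariates + confounders, reduced =
    the non-target terms. ``mode="IBD"``: full = target, reduced =
    intercept only. With empty covariate/confounder sets IBDCC degenerates
    exactly to IBD.
    """
    if mode not in ("IBD", "IBDCC"):
        raise ValidationError(f"unknown mode {mode!r}")
    target = target or meta.target
    meta = meta.aligned_to(table.sample_ids)
    if s is None:
        s = compute_size_factors(table)
    offset = s.log()[table.sample_ids].to_numpy()
    adjust = []
    if mode == "IBDCC":
        adjust = list(dict.fromkeys((covariates or []) + (confounders or [])))
    full_spec = DesignSpec(target, adjust)
    x_full = full_spec.matrix(meta)
    x_red = full_spec.reduced().matrix(meta)
    rows, skipped = [], {}
    for taxon in table.taxa_ids:
        y = table.data.loc[taxon].to_numpy()
        if not (y > 0).any():
            skipped[taxon] = "all-zero counts"
            continue
        out = _test_one_taxon(y, x_full, x_red, offset, families)
        if isinstance(out, str):
            skipped[taxon] = out
            continue
        fam, stat, df, p = out
        rows.append((taxon, fam, stat, df, p))
    if not rows:
        raise ValidationError("no taxon could be tested")
    res = pd.DataFrame(rows, columns=["taxon", "family", "lrt", "df",
                                      "p_value"]).set_index("taxon")
    res["adj_p"] = bh_adjust(res["p_value"].to_numpy())
    res["significant"] = res["adj_p"] < alpha
    return SuiteResult(mode, res, skipped, alpha)


# ---------------------------------------------------------------------------
# non-overlapping taxa and attribution
# ---------------------------------------------------------------------------

@dataclass
class NofReport:
    ibd_only: list[str]
    ibdcc_only: list[str]
    both: list[str]
    attribution: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def nofs(self) -> list[str]:
        return self.ibd_only + self.ibdcc_only


def identify_nofs(ibd: SuiteResult, ibdcc: SuiteResult) -> NofReport:
    """Split taxa by which of the two models calls them significant."""
    if set(ibd.results.index) != set(ibdcc.results.index):
        only = set(ibd.results.index) ^ set(ibdcc.results.index)
        raise ValidationError(f"taxa present in only one result list: {sorted(only)}")
    sig_ibd = set(ibd.significant_taxa)
    sig_cc = set(ibdcc.significant_taxa)
    order = list(ibd.results.index)
    return NofReport(
        ibd_only=[t for t in order if t in sig_ibd - sig_cc],
        ibdcc_only=[t for t in order if t in sig_cc - sig_ibd],
        both=[t for t in order if t in sig_ibd & sig_cc])


def attribute_nof(taxon: str, table: CountTable, meta: MetadataFrame,
                  target: str | None = None,
                  variables: list[str] | None = None,
                  s: SizeFactors | None = None,
                  alpha: float = 0.05,
                  families=FAMILIES) -> pd.DataFrame:
    """Single-variable attribution for one non-overlapping taxon.

    Approach 1 adds each variable alone to the target-only model and tests
    the target (LRT of target+v vs v); approach 2 removes each variable
    alone from the adjusted model (LRT of target+all−v vs all−v). A
    variable is *attributed* when approach-1 p ≥ alpha (adding it removes
    the target signal) and approach-2 p < alpha (excluding it restores
    the signal).
    """
    target = target or meta.target
    variables = list(variables or [])
    meta = meta.aligned_to(table.sample_ids)
    if s is None:
        s = compute_size_factors(table)
    offset = s.log()[table.sample_ids].to_numpy()
    y = table.data.loc[taxon].to_numpy()
    rows = []
    for v in variables:
        rest = [w for w in variables if w != v]
        p1 = p2 = np.nan
        out1 = _test_one_taxon(
            y, DesignSpec(target, [v]).matrix(meta),
            DesignSpec(None, [v]).matrix(meta), offset, families)
        if not isinstance(out1, str):
            p1 = out1[3]
        out2 = _test_one_taxon(
            y, DesignSpec(target, rest).matrix(meta),
            DesignSpec(None, rest).matrix(meta), offset, families)
        if not isinstance(out2, str):
            p2 = out2[3]
        attributed = bool(np.isfinite(p1) and np.isfinite(p2)
                          and p1 >= alpha and p2 < alpha)
        rows.append((v, p1, p2, attributed))
    return pd.DataFrame(rows, columns=["variable", "approach1_p",
                                       "approach2_p", "attributed"]
                        ).set_index("variable")


# ---------------------------------------------------------------------------
# subgroup analysis
# ---------------------------------------------------------------------------

@dataclass
class SubgroupBundle:
    screen: "object"
    covariates: "object"
    ibd: SuiteResult
    ibdcc: SuiteResult
    nofs: NofReport


def subgroup_analysis(table: CountTable, meta: MetadataFrame,
                      subgroup: str, control_level: str,
                      candidates: list[str],
                      case_levels: list[str] | None = None,
                      metrics: tuple[str, ...] = ("bray_curtis", "canberra"),
                      tree=None, n_perm: int = 999, seed: int = 0,
                      alpha: float = 0.05,
                      families=FAMILIES) -> SubgroupBundle:
    """Re-run the whole machinery with a multi-level subgroup as target.

    Samples are restricted to the control level plus the case levels (all
    other observed levels by default); small levels are retained with a
    warning rather than dropped.
    """
    from .diversity import beta_distance
    from .preprocessing import normalize
    from .variable_screen import stepwise_covariate_selection, unbalance_screen

    levels = list(dict.fromkeys(meta.data[subgroup]))
    if case_levels is None:
        case_levels = [l for l in levels if l != control_level]
    if len(case_levels) < 2:
        raise ValidationError("need a control level plus >=2 case levels")
    keep = meta.data[subgroup].isin([control_level] + case_levels)
    for lev in [control_level] + case_levels:
        n_lev = int((meta.data[subgroup] == lev).sum())
        if n_lev < 2:
            warnings.warn(f"subgroup level {lev!r} has only {n_lev} sample(s); retained")
    sub_samples = list(meta.data.index[keep])
    sub_table = table.select_samples(sub_samples)
    sub_meta = MetadataFrame(meta.data.loc[sub_samples].copy(),
                             dict(meta.schema), target=subgroup,
                             subgroup=None,
                             levels={k: list(v) for k, v in meta.levels.items()})
    sub_meta.levels[subgroup] = [control_level] + case_levels
    s = compute_size_factors(sub_table)
    screen = unbalance_screen(sub_meta, target=subgroup,
                              variables=candidates, alpha=alpha, seed=seed)
    norm = normalize(sub_table, s)
    distances = {m: beta_distance(norm, m, tree=tree) for m in metrics}
    covset = stepwise_covariate_selection(
        distances, sub_meta, candidates, target=subgroup, alpha=alpha,
        n_perm=n_perm, seed=seed)
    confounders = [v for v in screen.confounders if v not in covset.union]
    ibd = run_model_suite(sub_table, sub_meta, target=subgroup, s=s,
                          mode="IBD", alpha=alpha, families=families)
    ibdcc = run_model_suite(sub_table, sub_meta, target=subgroup,
                            covariates=covset.union, confounders=confounders,
                            s=s, mode="IBDCC", alpha=alpha, families=families)
    nofs = identify_nofs(ibd, ibdcc)
    return SubgroupBundle(screen, covset, ibd, ibdcc, nofs)
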