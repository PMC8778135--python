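import numpy as np
import pandas as pd
import pytest

import microconfound.diff_abundance as da_mod
from microconfound.data_model import CountTable, MetadataFrame, ValidationError
from microconfound.diff_abundance import (
    DesignSpec, GlmFit, attribute_nof, bh_adjust, fit_taxon_glm,
    identify_nofs, lrt_compare, run_model_suite, select_distribution,
    subgroup_analysis,
)
from microconfound.synthetic_data import (
    SyntheticConfig, generate_cohort, taxon_names,
)


def simple_design(x):
    return pd.DataFrame({"Intercept": np.ones(len(x)), "x": x})


class TestFitTaxonGlm:
    def test_poisson_parameter_recovery(self):
        rng = np.random.default_rng(1)
        n = 500
        x = rng.integers(0, 2, n).astype(float)
        y = rng.poisson(np.exp(1.0 + 0.8 * x))
        fit = fit_taxon_glm(y, simple_design(x), np.zeros(n), "poisson")
        assert fit.converged
        assert fit.params["x"] == pytest.approx(0.8, abs=0.1)

    def test_intercept_only_poisson_closed_form(self):
        rng = np.random.default_rng(2)
        n = 80
        off = rng.normal(0, 0.3, n)
        y = rng.poisson(np.exp(1.5 + off))
        design = pd.DataFrame({"Intercept": np.ones(n)})
        fit = fit_taxon_glm(y, design, off, "poisson")
        # MLE: exp(b0) = sum(y) / sum(exp(offset))
        assert fit.params["Intercept"] == pytest.approx(
            np.log(y.sum() / np.exp(off).sum()), abs=1e-6)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError, match="all-zero"):
            fit_taxon_glm(np.zeros(10, dtype=int),
                          simple_design(np.zeros(10)), np.zeros(10), "nb")

    def test_hurdle_without_zeros_flagged(self):
        rng = np.random.default_rng(3)
        y = rng.poisson(20.0, 60) + 1
        x = rng.integers(0, 2, 60).astype(float)
        fit = fit_taxon_glm(y, simple_design(x), np.zeros(60), "hurdle")
        assert not fit.converged
        assert any("zero" in f for f in fit.flags)

    def test_bic_consistent_with_parts(self):
        rng = np.random.default_rng(4)
        n = 100
        x = rng.integers(0, 2, n).astype(float)
        mu = np.exp(2.0 + 0.5 * x)
        y = rng.negative_binomial(1.0, 1.0 / (1.0 + mu))
        for fam in ("poisson", "nb", "zinb", "hurdle"):
            fit = fit_taxon_glm(y, simple_design(x), np.zeros(n), fam)
            if not fit.converged:
                continue
            assert fit.bic == pytest.approx(
                -2 * fit.loglik + fit.n_params * np.log(n), abs=1e-8)

    def test_nb_matches_statsmodels_directly(self):
        from statsmodels.discrete.discrete_model import NegativeBinomial
        rng = np.random.default_rng(5)
        n = 200
        x = rng.integers(0, 2, n).astype(float)
        mu = np.exp(2.0 + 0.7 * x)
        y = rng.negative_binomial(1.5, 1.5 / (1.5 + mu))
        ours = fit_taxon_glm(y, simple_design(x), np.zeros(n), "nb")
        X = np.column_stack([np.ones(n), x])
        ref = NegativeBinomial(y, X).fit(disp=0, maxiter=500)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-4)


class TestSelectDistribution:
    def test_overdispersed_prefers_nb_family(self):
        rng = np.random.default_rng(6)
        n = 300
        x = rng.integers(0, 2, n).astype(float)
        mu = np.exp(3.0 + 0.3 * x)
        wins = 0
        for _ in range(20):
            y = rng.negative_binomial(0.5, 0.5 / (0.5 + mu))
            best, _ = select_distribution(y, simple_design(x), np.zeros(n))
            wins += best in ("nb", "zinb")
        assert wins >= 19

    def test_poisson_data_prefers_poisson_plurality(self):
        rng = np.random.default_rng(7)
        n = 300
        x = rng.integers(0, 2, n).astype(float)
        mu = np.exp(2.0 + 0.4 * x)
        chosen = []
        for _ in range(20):
            y = rng.poisson(mu)
            best, _ = select_distribution(y, simple_design(x), np.zeros(n))
            chosen.append(best)
        counts = pd.Series(chosen).value_counts()
        assert counts.index[0] == "poisson"

    def test_bic_tie_goes_to_simplest(self, monkeypatch):
        def fake_fit(y, design, offset, family):
            return GlmFit(family, pd.Series(dtype=float),
                          pd.Series(dtype=float), loglik=-50.0, n_params=3,
                          n_obs=20, converged=True)
        monkeypatch.setattr(da_mod, "fit_taxon_glm", fake_fit)
        best, fits = select_distribution(
            np.ones(20, dtype=int), pd.DataFrame({"Intercept": np.ones(20)}),
            np.zeros(20))
        assert best == "poisson"
        assert all(f.bic == fits["poisson"].bic for f in fits.values())


class TestLrt:
    def test_identical_models(self):
        fit = GlmFit("nb", pd.Series(dtype=float), pd.Series(dtype=float),
                     -10.0, 3, 50, True)
        assert lrt_compare(fit, fit) == (0.0, 0, 1.0)

    def test_family_mismatch_error(self):
        a = GlmFit("nb", pd.Series(dtype=float), pd.Series(dtype=float),
                   -10.0, 3, 50, True)
        b = GlmFit("poisson", pd.Series(dtype=float), pd.Series(dtype=float),
                   -12.0, 2, 50, True)
        with pytest.raises(ValidationError, match="family"):
            lrt_compare(a, b)

    def test_invariant_to_level_recoding(self):
        """LRT statistic must not depend on the categorical reference level."""
        cfg = SyntheticConfig.confounded(n_per_group=15, n_taxa=6, seed=8)
        table, meta, *_ = generate_cohort(cfg)
        y = table.data.loc["fam001"].to_numpy()
        off = np.zeros(len(y))
        stats_out = []
        for order in (["HC", "CD", "UC"], ["UC", "HC", "CD"]):
            meta.levels["group"] = order
            full = DesignSpec("group", []).matrix(meta)
            red = DesignSpec(None, []).matrix(meta)
            f1 = fit_taxon_glm(y, full, off, "poisson")
            f0 = fit_taxon_glm(y, red, off, "poisson")
            stats_out.append(lrt_compare(f1, f0)[0])
        assert stats_out[0] == pytest.approx(stats_out[1], abs=1e-6)


class TestBhAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.4])[0] == pytest.approx(0.4)

    def test_against_brute_force_and_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            ours = bh_adjust(p)
            # brute force: min over k >= rank of m * p_(k) / k
            m = len(p)
            order = np.argsort(p)
            brute = np.empty(m)
            sorted_p = p[order]
            for i in range(m):
                brute[order[i]] = min(1.0, (sorted_p[i:] * m /
                                            np.arange(i + 1, m + 1)).min())
            np.testing.assert_allclose(ours, brute, atol=1e-12)
            np.testing.assert_allclose(
                ours, multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_invalid_input(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])


class TestModelSuite:
    def test_ibdcc_without_adjustment_equals_ibd(self, small_cohort):
        table, meta = small_cohort[0], small_cohort[1]
        ibd = run_model_suite(table, meta, mode="IBD")
        ibdcc = run_model_suite(table, meta, covariates=[], confounders=[],
                                mode="IBDCC")
        pd.testing.assert_frame_equal(ibd.results, ibdcc.results)

    def test_direct_group_effect_found_in_both_modes(self, small_cohort):
        """Directly group-driven taxa survive adjustment; at this small n the
        strongly group-collinear cereals term costs power, so only the
        stronger planted signal is asserted under the adjusted model."""
        table, meta = small_cohort[0], small_cohort[1]
        ibd = run_model_suite(table, meta, mode="IBD")
        ibdcc = run_model_suite(table, meta, covariates=["cereals"],
                                confounders=[], mode="IBDCC")
        assert {"fam001", "fam002"} <= set(ibd.significant_taxa)
        assert "fam002" in ibdcc.significant_taxa

    def test_all_zero_taxon_skipped(self, small_cohort):
        table, meta = small_cohort[0], small_cohort[1]
        dead = table.data.copy()
        dead.loc["empty"] = 0
        suite = run_model_suite(CountTable(dead), meta, mode="IBD")
        assert suite.skipped["empty"] == "all-zero counts"

    def test_level_with_all_zero_counts_does_not_crash(self):
        cfg = SyntheticConfig.confounded(n_per_group=15, n_taxa=6, seed=9)
        table, meta, *_ = generate_cohort(cfg)
        zeroed = table.data.copy()
        zeroed.loc["fam004", meta.data["group"] == "CD"] = 0
        suite = run_model_suite(CountTable(zeroed), meta, mode="IBD")
        assert "fam004" in set(suite.results.index) | set(suite.skipped)


class TestNofs:
    def _mk(self, flags, mode):
        res = pd.DataFrame({
            "family": "nb", "lrt": 1.0, "df": 2,
            "p_value": [0.01 if f else 0.5 for f in flags.values()],
            "adj_p": [0.01 if f else 0.5 for f in flags.values()],
            "significant": list(flags.values())},
            index=pd.Index(flags.keys(), name="taxon"))
        return da_mod.SuiteResult(mode, res)

    def test_identical_flags_no_nofs(self):
        flags = {"A": True, "B": False}
        rep = identify_nofs(self._mk(flags, "IBD"), self._mk(flags, "IBDCC"))
        assert rep.both == ["A"] and rep.nofs == []

    def test_set_difference(self):
        rep = identify_nofs(self._mk({"A": True, "B": True}, "IBD"),
                            self._mk({"A": False, "B": True}, "IBDCC"))
        assert rep.ibd_only == ["A"] and rep.both == ["B"]

    def test_mismatched_taxa_error(self):
        with pytest.raises(ValidationError, match="only one"):
            identify_nofs(self._mk({"A": True}, "IBD"),
                          self._mk({"B": True}, "IBDCC"))

    def test_empty_variable_list_attribution(self, small_cohort):
        table, meta = small_cohort[0], small_cohort[1]
        out = attribute_nof("fam001", table, meta, variables=[])
        assert out.empty


class TestSubgroupAnalysis:
    def test_gradient_coefficients_monotone(self):
        """Planted E1<E2<E3 effect is recovered in sign and ordering."""
        names = taxon_names(6)
        variables = {"yogurt": {g: 0.5 for g in ("HC", "E1", "E2", "E3")}}
        cfg = SyntheticConfig(
            group_sizes={"HC": 25, "E1": 25, "E2": 25, "E3": 25},
            subgroup_sizes=None, n_taxa=6,
            baseline_logmean=-5.5, dispersion=2.0, zero_inflation=0.0,
            library_sdlog=0.0,
            group_effects={names[0]: {"E1": 0.6, "E2": 1.2, "E3": 1.8}},
            variables=variables,
            age_by_group={g: (45.0, 13.0) for g in ("HC", "E1", "E2", "E3")},
            seed=55)
        table, meta, *_ = generate_cohort(cfg)
        y = table.data.loc[names[0]].to_numpy()
        design = DesignSpec("group", []).matrix(meta)
        fit = fit_taxon_glm(y, design, np.zeros(len(y)), "nb")
        coefs = [fit.params[f"group[{lev}]"] for lev in ("E1", "E2", "E3")]
        assert all(c > 0 for c in coefs)
        assert coefs[0] < coefs[1] < coefs[2]

    def test_bundle_runs_end_to_end(self):
        cfg = SyntheticConfig.confounded(n_per_group=15, n_taxa=6, seed=10)
        table, meta, *_ = generate_cohort(cfg)
        bundle = subgroup_analysis(
            table, meta, subgroup="group", control_level="HC",
            candidates=["cereals", "yogurt"], n_perm=49, seed=0)
        assert set(bundle.ibd.results.index) == set(bundle.ibdcc.results.index)
        assert bundle.nofs is not None

    def test_tiny_level_warns_but_retained(self):
        cfg = SyntheticConfig.confounded(n_per_group=15, n_taxa=6, seed=11)
        table, meta, *_ = generate_cohort(cfg)
        # shrink one case level to a single sample
        meta.data["subgroup2"] = meta.data["group"].astype(str)
        meta.data.loc[meta.data["group"] == "CD", "subgroup2"] = "B2"
        first_cd = meta.data.index[meta.data["group"] == "CD"][0]
        meta.data["subgroup2"] = meta.data["subgroup2"].replace({"UC": "B1"})
        meta.data.loc[first_cd, "subgroup2"] = "B3"
        meta.schema["subgroup2"] = "categorical"
        meta.levels["subgroup2"] = ["HC", "B1", "B2", "B3"]
        with pytest.warns(UserWarning, match="retained"):
            subgroup_analysis(table, meta, subgroup="subgroup2",
                              control_level="HC",
                              candidates=["yogurt"], n_perm=49, seed=0)
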