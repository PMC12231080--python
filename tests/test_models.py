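import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from fireprogress.models import (fit_cover_contrasts, fit_fpe_covariate_lm,
                                 fit_fpe_doy_smooth, fit_mixed,
                                 prepare_response, select_model)

from conftest import synth_patch_table


class TestPrepareResponse:
    def _table(self):
        return pd.DataFrame({
            "fire_id": ["a", "a", "b", "b"],
            "area_ha": [100.0, 9.0, 0.09, 1.0],
            "max_linear_spread_m": [300.0, 0.0, 42.0, 15.0],
            "aspen": [0.07, 0.0005, 0.2, 0.003],
        })

    def test_log10_area(self):
        out = prepare_response(self._table())
        assert out["log10_area_ha"].iloc[0] == pytest.approx(2.0)

    def test_zero_spread_floored_at_half_pixel(self):
        out = prepare_response(self._table())
        assert out["log10_linear_m"].iloc[1] == pytest.approx(np.log10(15.0))

    def test_aspen_subset_flags(self):
        out = prepare_response(self._table())
        row = out.iloc[0]  # 7% aspen
        assert row["aspen_present"] and row["gt5"] and not row["gt10"]
        assert not out.iloc[1]["aspen_present"]  # 0.05% aspen

    def test_empty_table_is_error(self):
        with pytest.raises(ValueError):
            prepare_response(pd.DataFrame())


class TestFitMixed:
    def test_recovers_known_negative_slope(self):
        rng = np.random.default_rng(10)
        table = synth_patch_table(rng, slope=-0.008)
        res = fit_mixed(table, "y", ["aspen_pct"])
        fe = res.effect("aspen_pct")
        assert abs(fe.estimate - (-0.008)) <= 2 * fe.se
        assert fe.p_value < 0.05
        assert res.random_effect_variance > 0

    def test_zero_random_variance_matches_ols(self):
        rng = np.random.default_rng(11)
        table = synth_patch_table(rng, intercept_sd=0.0, slope=-0.01)
        res = fit_mixed(table, "y", ["aspen_pct"])
        X = sm.add_constant(table[["aspen_pct"]])
        ols = sm.OLS(table["y"], X).fit()
        assert res.effect("aspen_pct").estimate == pytest.approx(
            ols.params["aspen_pct"], abs=5e-4)

    def test_variance_explained_partition(self):
        rng = np.random.default_rng(12)
        table = synth_patch_table(rng, slope=-0.008)
        res = fit_mixed(table, "y", ["aspen_pct"])
        assert 0 < res.r2_marginal < res.r2_conditional < 1

    def test_preconditions(self):
        rng = np.random.default_rng(13)
        table = synth_patch_table(rng, n_fires=1)
        with pytest.raises(ValueError):
            fit_mixed(table, "y", ["aspen_pct"])
        with pytest.raises(ValueError):
            fit_mixed(synth_patch_table(rng, n_fires=2, patches_per_fire=2),
                      "y", ["aspen_pct"])


class TestCoverContrasts:
    def test_duplicated_column_gives_identical_coefficients(self):
        rng = np.random.default_rng(14)
        table = synth_patch_table(rng, slope=-0.01)
        table["copy_a"] = table["aspen_pct"]
        results, skipped = fit_cover_contrasts(table, ["aspen_pct", "copy_a"], "y")
        a = results["aspen_pct"].effect("aspen_pct").estimate
        b = results["copy_a"].effect("copy_a").estimate
        assert a == pytest.approx(b, abs=1e-8)
        assert skipped == []

    def test_constant_proportion_type_skipped(self):
        rng = np.random.default_rng(15)
        table = synth_patch_table(rng)
        table["wetland"] = 0.0
        results, skipped = fit_cover_contrasts(table, ["wetland"], "y")
        assert skipped == ["wetland"] and results == {}

    def test_contrast_signs_reflect_generative_truth(self):
        # aspen lowers the response; its complement must raise it
        rng = np.random.default_rng(16)
        table = synth_patch_table(rng, slope=-0.01)
        table["warm_pct"] = 60.0 - table["aspen_pct"]
        results, _ = fit_cover_contrasts(table, ["aspen_pct", "warm_pct"], "y")
        assert results["aspen_pct"].effect("aspen_pct").estimate < 0
        assert results["warm_pct"].effect("warm_pct").estimate > 0


class TestSelectModel:
    def _table_with_covariates(self, rng, n_fires=20, patches=20, fwi_slope=0.3):
        table = synth_patch_table(rng, n_fires=n_fires, patches_per_fire=patches,
                                  slope=-0.008)
        n = len(table)
        table["FWI"] = rng.normal(size=n)
        table["y"] = table["y"] + fwi_slope * table["FWI"]
        return table

    def test_perfectly_correlated_copies_pruned_to_one(self):
        rng = np.random.default_rng(17)
        table = self._table_with_covariates(rng)
        table["FWI_copy"] = table["FWI"]
        res, trace = select_model(table, "y", ["aspen_pct", "FWI", "FWI_copy"],
                                  focal="aspen_pct")
        terms = [fe.term for fe in res.fixed_effects]
        assert ("FWI" in terms) != ("FWI_copy" in terms)  # exactly one survives
        assert any(a == "drop_collinear" for a, _, _ in trace.steps)

    def test_pure_noise_terms_survive_at_alpha_rate(self):
        """Type-I calibration: each of three independent noise covariates
        should survive selection with probability ~ alpha = 0.05."""
        rng = np.random.default_rng(18)
        survived = trials = 0
        for _ in range(60):
            table = synth_patch_table(rng, n_fires=15, patches_per_fire=15,
                                      slope=-0.008)
            n = len(table)
            for name in ("n1", "n2", "n3"):
                table[name] = rng.normal(size=n)
            res, _ = select_model(table, "y", ["aspen_pct", "n1", "n2", "n3"],
                                  focal="aspen_pct")
            terms = {fe.term for fe in res.fixed_effects}
            survived += len(terms & {"n1", "n2", "n3"})
            trials += 3
        # 180 Bernoulli(0.05) trials: expect 9, keep within ~3.5 sigma
        assert 1 <= survived <= 20

    def test_null_interaction_rarely_retained(self):
        """With no true aspen x weather interaction the selected model
        excludes the interaction term in nearly all replicates."""
        rng = np.random.default_rng(19)
        kept = 0
        n_rep = 20
        for _ in range(n_rep):
            table = self._table_with_covariates(rng)
            res, _ = select_model(table, "y", ["aspen_pct", "FWI"],
                                  focal="aspen_pct")
            if any(":" in fe.term for fe in res.fixed_effects):
                kept += 1
        assert kept <= n_rep - 16  # >= 80% exclusion

    def test_true_interaction_detected_and_aic_improves(self):
        rng = np.random.default_rng(20)
        table = self._table_with_covariates(rng, n_fires=30, patches=20)
        table["y"] = table["y"] + 0.01 * table["aspen_pct"] * table["FWI"]
        res, trace = select_model(table, "y", ["aspen_pct", "FWI"],
                                  focal="aspen_pct")
        assert any(a == "add_interaction" for a, _, _ in trace.steps)

    def test_selected_aic_never_worse_than_initial(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            table = self._table_with_covariates(rng)
            table["noise"] = rng.normal(size=len(table))
            initial = fit_mixed(table, "y", ["aspen_pct", "FWI", "noise"])
            res, _ = select_model(table, "y", ["aspen_pct", "FWI", "noise"],
                                  focal="aspen_pct")
            assert res.aic <= initial.aic + 1e-9


class TestFPECovariateLM:
    def _frame(self, rng, n=60, slope=0.5, noise=0.1):
        cov = rng.normal(size=n)
        return pd.DataFrame({
            "fpe": slope * cov + rng.normal(0, noise, n),
            "FWI": cov,
        })

    def test_slope_recovered_within_two_se(self):
        rng = np.random.default_rng(22)
        out = fit_fpe_covariate_lm(self._frame(rng), ["FWI"])
        row = out.iloc[0]
        assert abs(row["slope"] - 0.5) <= 2 * row["se"]

    def test_too_few_fires_is_error(self):
        rng = np.random.default_rng(23)
        with pytest.raises(ValueError):
            fit_fpe_covariate_lm(self._frame(rng, n=2), ["FWI"])

    def test_constant_covariate_skipped(self):
        rng = np.random.default_rng(24)
        df = self._frame(rng)
        df["flat"] = 1.0
        out = fit_fpe_covariate_lm(df, ["flat"])
        assert out.empty

    def test_null_p_values_uniform(self):
        """With FPE independent of the covariate, slope p-values are
        Uniform(0, 1) (Kolmogorov-Smirnov sanity at 150 replicates)."""
        rng = np.random.default_rng(25)
        ps = []
        for _ in range(150):
            df = pd.DataFrame({"fpe": rng.normal(size=40),
                               "FWI": rng.normal(size=40)})
            ps.append(fit_fpe_covariate_lm(df, ["FWI"])["p_value"].iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestFPEDOYSmooth:
    def test_constant_fpe_gives_flat_nonsignificant_smooth(self):
        rng = np.random.default_rng(26)
        doy = rng.uniform(120, 300, 120)
        fpe = 0.2 + rng.normal(0, 0.1, 120)
        res = fit_fpe_doy_smooth(fpe, doy)
        assert res.p_value > 0.05
        assert res.edf < 3.0  # smooth collapses toward a constant

    def test_seasonal_signal_detected(self):
        rng = np.random.default_rng(27)
        sig = 0
        for _ in range(10):
            doy = rng.uniform(100, 320, 300)
            fpe = 0.3 * np.sin(2 * np.pi * doy / 365) + rng.normal(0, 0.2, 300)
            res = fit_fpe_doy_smooth(fpe, doy)
            sig += res.p_value < 0.05
        assert sig >= 9

    def test_fitted_curve_recovers_sinusoid_within_bands(self):
        rng = np.random.default_rng(28)
        doy = rng.uniform(100, 320, 300)
        fpe = 0.3 * np.sin(2 * np.pi * doy / 365) + rng.normal(0, 0.2, 300)
        res = fit_fpe_doy_smooth(fpe, doy)
        truth = 0.3 * np.sin(2 * np.pi * res.grid / 365)
        inside = (truth >= res.ci_low) & (truth <= res.ci_high)
        assert inside.mean() >= 0.8

    def test_preconditions(self):
        rng = np.random.default_rng(29)
        with pytest.raises(ValueError, match="20"):
            fit_fpe_doy_smooth(rng.normal(size=10), rng.uniform(100, 300, 10))
        with pytest.raises(ValueError, match="60"):
            fit_fpe_doy_smooth(rng.normal(size=30), rng.uniform(200, 210, 30))
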