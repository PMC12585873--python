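"""Piecewise path model, total effects, slope model, and the synthetic
results-table generator that serves as their oracle."""

import numpy as np
import pandas as pd
import pytest

from webstab.pathmodel import (
    SlopeModelFit,
    fit_path_model,
    fit_slope_model,
    generate_synthetic_table,
    richness_slope,
    total_effects,
)


class TestStandardizedCoefficients:
    def test_equals_pearson_r_with_single_predictor(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        y = 0.4 * x + rng.normal(size=500)
        table = pd.DataFrame({"x": x, "y": y})
        fit = fit_path_model(table, {"y": ["x"]})
        assert fit.rdelta[("y", "x")] == pytest.approx(
            np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_identity_relation_gives_unit_coefficient(self):
        rng = np.random.default_rng(1)
        x = rng.normal(2.0, 3.0, 300)
        table = pd.DataFrame({"x": x, "y": x.copy()})
        fit = fit_path_model(table, {"y": ["x"]})
        assert fit.rdelta[("y", "x")] == pytest.approx(1.0)

    def test_rank_deficiency_raises(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        table = pd.DataFrame({"x": x, "x2": 2 * x, "y": x + 1})
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_path_model(table, {"y": ["x", "x2"]})

    def test_cycle_rejected(self):
        table = pd.DataFrame({"x": [1.0, 2, 3], "y": [2.0, 1, 3]})
        with pytest.raises(ValueError, match="cycle"):
            fit_path_model(table, {"y": ["x"], "x": ["y"]})


class TestTotalEffects:
    def test_chain_with_direct_edge(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20_000)
        m = 0.6 * x + rng.normal(0, 0.4, x.size)
        y = 0.5 * m + 0.3 * x + rng.normal(0, 0.3, x.size)
        table = pd.DataFrame({"x": x, "m": m, "y": y})
        fit = fit_path_model(table, {"m": ["x"], "y": ["x", "m"]})
        tot = total_effects(fit)
        expected = fit.rdelta[("y", "x")] + \
            fit.rdelta[("m", "x")] * fit.rdelta[("y", "m")]
        assert tot[("x", "y")] == pytest.approx(expected, abs=1e-12)

    def test_total_effect_equals_reduced_form(self):
        # in a linear Gaussian system the path-summed standardized effect of
        # an exogenous variable equals its reduced-form coefficient
        table, _ = generate_synthetic_table(n=40_000, noise_sd=0.05, seed=4)
        fit = fit_path_model(table)
        tot = total_effects(fit)
        exog = ["sigma_e", "response_diversity", "richness", "wtl",
                "connectance", "interaction_strength", "ppmr", "interference"]
        import statsmodels.api as sm

        reduced = sm.OLS(table["log_s_com"],
                         sm.add_constant(table[exog])).fit()
        sds = table.std(ddof=1)
        for v in ("sigma_e", "response_diversity"):
            std_coef = reduced.params[v] * sds[v] / sds["log_s_com"]
            assert tot[(v, "log_s_com")] == pytest.approx(std_coef, abs=0.03)

    def test_unreachable_pairs_absent(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(rng.normal(size=(100, 3)), columns=["a", "b", "c"])
        fit = fit_path_model(table, {"c": ["a", "b"]})
        tot = total_effects(fit)
        assert ("c", "a") not in tot
        assert ("a", "b") not in tot


class TestRecovery:
    def test_noiseless_recovery_is_exact(self):
        table, truth = generate_synthetic_table(n=2000, noise_sd=0.0, seed=6)
        fit = fit_path_model(table)
        for resp, preds in truth.items():
            for pred, b in preds.items():
                if (resp, pred) in fit.coefficients:
                    assert fit.coefficients[(resp, pred)] == \
                        pytest.approx(b, abs=1e-8)

    def test_standardized_recovery_at_realistic_noise(self):
        table, truth = generate_synthetic_table(n=5000, noise_sd=0.1, seed=7)
        fit = fit_path_model(table)
        sds = table.std(ddof=1)
        for resp, preds in truth.items():
            for pred, b in preds.items():
                if (resp, pred) not in fit.rdelta:
                    continue
                truth_std = b * sds[pred] / sds[resp]
                assert fit.rdelta[(resp, pred)] == \
                    pytest.approx(truth_std, abs=0.03)

    def test_consistency_at_large_n(self):
        table, truth = generate_synthetic_table(n=100_000, noise_sd=0.2,
                                                seed=8)
        fit = fit_path_model(table)
        assert fit.coefficients[("log_pfe", "response_diversity")] == \
            pytest.approx(truth["log_pfe"]["response_diversity"], abs=0.01)

    def test_design_grid_sds_in_synthetic_table(self):
        table, _ = generate_synthetic_table(n=50_000, seed=9)
        assert table["sigma_e"].std(ddof=0) == pytest.approx(0.1708, abs=0.005)
        assert table["response_diversity"].std(ddof=0) == \
            pytest.approx(0.3536, abs=0.005)


class TestSlopeModel:
    def test_slope_algebra_main_effect_only(self):
        fit = SlopeModelFit(coefficients={("richness",): 0.7},
                            centres={}, vif={}, method="ols", n=10)
        assert richness_slope(fit, {}) == pytest.approx(0.7)

    def test_slope_algebra_with_interaction(self):
        fit = SlopeModelFit(
            coefficients={("richness",): 0.2,
                          ("richness", "response_diversity"): 0.5},
            centres={"response_diversity": 0.5}, vif={}, method="ols", n=10)
        assert richness_slope(fit, {"response_diversity": 0.9}) == \
            pytest.approx(0.2 + 0.5 * 0.4)

    def test_missing_covariate_raises(self):
        fit = SlopeModelFit(
            coefficients={("richness", "wtl"): 1.0},
            centres={"wtl": 1.5}, vif={}, method="ols", n=10)
        with pytest.raises(KeyError):
            richness_slope(fit, {})

    def test_zero_interaction_structure_recovered(self):
        rng = np.random.default_rng(10)
        n = 6000
        table = pd.DataFrame({
            "web_id": np.arange(n) // 5,
            "richness": rng.integers(3, 30, n).astype(float),
            "wtl": rng.uniform(1, 3, n),
            "connectance": rng.uniform(0.02, 0.38, n),
            "interaction_strength": rng.uniform(0.001, 0.08, n),
            "sigma_e": rng.choice([0.1, 0.3, 0.6], n),
            "response_diversity": rng.choice([0.0, 0.5, 1.0], n),
            "ppmr": rng.uniform(1, 100, n),
            "interference": rng.uniform(0, 1, n),
        })
        table["log_s_com"] = (0.05 * table["richness"]
                              - 2.0 * table["sigma_e"]
                              + rng.normal(0, 0.1, n))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_slope_model(table)
        for term, coef in fit.coefficients.items():
            if "richness" in term and len(term) > 1:
                assert abs(coef) < 0.05
        cov = {"wtl": 2.0, "connectance": 0.2, "interaction_strength": 0.04,
               "sigma_e": 0.3, "response_diversity": 0.5}
        assert richness_slope(fit, cov) == pytest.approx(0.05, abs=0.005)

    def test_demeaning_fallback_available(self):
        table, _ = generate_synthetic_table(n=3000, noise_sd=0.1, seed=11)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_slope_model(table, method="demean")
        assert fit.method == "demean"
        assert np.isfinite(list(fit.coefficients.values())).all()
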