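"""Association layer: partial correlation, trend/chi-square, regressions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dietrrr as d


class TestPartialCorrelation:
    def test_reduces_to_pearson_when_inputs_orthogonal_to_control(self, rng):
        c = rng.normal(size=60)
        a = rng.normal(size=60)
        b = 0.5 * a + rng.normal(size=60)
        # orthogonalize a, b against c in-sample
        for v in (a, b):
            v -= np.polyval(np.polyfit(c, v, 1), c)
        res = d.partial_correlation(a, b, c)
        assert res.estimate == pytest.approx(np.corrcoef(a, b)[0, 1], abs=1e-10)

    def test_control_equal_to_input_is_degenerate(self, rng):
        c = rng.normal(size=30)
        a = rng.normal(size=30)
        with pytest.raises(ValueError, match="zero-variance residual"):
            d.partial_correlation(a, c, c)

    def test_constant_control_falls_back_to_pearson(self, rng):
        a, b = rng.normal(size=40), rng.normal(size=40)
        res = d.partial_correlation(a, b, np.ones(40))
        assert res.estimate == pytest.approx(np.corrcoef(a, b)[0, 1], abs=1e-12)

    def test_five_point_hand_example_matches_pingouin(self):
        df = pd.DataFrame(
            {
                "a": [2.0, 4.0, 6.0, 7.0, 10.0],
                "b": [1.0, 3.0, 2.0, 6.0, 8.0],
                "c": [10.0, 12.0, 11.0, 15.0, 18.0],
            }
        )
        res = d.partial_correlation(df["a"], df["b"], df["c"])
        import pingouin as pg

        ref = pg.partial_corr(df, x="a", y="b", covar="c")
        p_col = "p_val" if "p_val" in ref.columns else "p-val"
        assert res.estimate == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)
        assert res.p_value == pytest.approx(float(ref[p_col].iloc[0]), abs=1e-6)

    def test_p_value_in_unit_interval(self, rng):
        res = d.partial_correlation(rng.normal(size=25), rng.normal(size=25), rng.normal(size=25))
        assert 0.0 <= res.p_value <= 1.0


class TestQuintileTrend:
    def test_flat_outcome(self):
        q = np.repeat([1, 2, 3, 4, 5], 4)
        res = d.quintile_trend_test(np.full(20, 7.0), q)
        assert res.estimate == 0.0 and res.p_value == pytest.approx(1.0)

    def test_exact_linearity(self):
        q = np.repeat([1, 2, 3, 4, 5], 4)
        res = d.quintile_trend_test(2.0 * q, q)
        assert res.estimate == pytest.approx(2.0) and res.p_value < 1e-10

    def test_ten_point_hand_ols(self, rng):
        q = np.repeat([1, 2, 3, 4, 5], 2)
        y = 1.5 * q + rng.normal(size=10)
        res = d.quintile_trend_test(y, q)
        slope, intercept = np.polyfit(q, y, 1)
        assert res.estimate == pytest.approx(slope, abs=1e-6)

    def test_energy_adjustment_changes_estimate(self, rng):
        q = np.repeat([1, 2, 3, 4, 5], 20)
        energy = 100.0 * q + rng.normal(0, 10, 100)
        y = 0.01 * energy + rng.normal(0, 0.1, 100)
        raw = d.quintile_trend_test(y, q)
        adj = d.quintile_trend_test(y, q, adjust_energy=True, energy=energy)
        assert abs(adj.estimate) < abs(raw.estimate)
        assert adj.covariates == ["energy"]

    def test_single_quintile_errors(self):
        with pytest.raises(ValueError):
            d.quintile_trend_test([1.0, 2.0, 3.0], [2, 2, 2])

    def test_trend_invariant_to_affine_relabeling(self, rng):
        q = np.repeat([1, 2, 3, 4, 5], 6)
        y = 0.7 * q + rng.normal(0, 0.5, 30)
        base = d.quintile_trend_test(y, q)
        scaled = d.quintile_trend_test(y, 10 + 2 * q)
        assert scaled.estimate == pytest.approx(base.estimate / 2.0, abs=1e-10)


class TestChiSquare:
    def test_hand_two_by_two(self):
        cat = np.repeat(["a", "b"], 10)
        q = np.concatenate([np.full(10, 1), np.full(10, 2)])
        res = d.categorical_quintile_test(cat, q)
        assert res.estimate == pytest.approx(20.0)
        assert res.notes["dof"] == 1

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(200):
            cat = rng.choice(["a", "b"], size=300)
            q = np.tile([1, 2, 3, 4, 5], 60)
            pvals.append(d.categorical_quintile_test(cat, q).p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 1e-3

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            d.categorical_quintile_test(["a", "a", "a"], [1, 2, 3])
        with pytest.raises(ValueError):
            d.categorical_quintile_test(["a", "b", "a"], [1, 1, 1])

    def test_low_expected_counts_flagged(self):
        cat = ["a"] * 18 + ["b"] * 2
        q = [1, 2] * 10
        res = d.categorical_quintile_test(cat, q)
        assert res.notes["low_expected_cells"] > 0


def _covariate_table(rng, n):
    return pd.DataFrame(
        {
            "age": rng.uniform(20, 80, n),
            "energy_kcal": rng.normal(2200, 300, n),
            "pir": rng.uniform(0, 5, n),
            "bmi": rng.normal(28, 5, n),
            "race": rng.choice(["w", "b", "h"], n),
            "education": rng.choice(["hs", "college"], n),
            "vigorous_work": rng.integers(0, 2, n),
            "vigorous_rec": rng.integers(0, 2, n),
            "lipid_med": rng.integers(0, 2, n),
            "supplement": rng.integers(0, 2, n),
        }
    )


class TestOutcomeRegression:
    def test_model1_recovers_slope(self, rng):
        n = 400
        score = rng.normal(size=n)
        y = 25 - 0.8 * score + rng.normal(0, 1, n)
        res = d.outcome_regression(y, score, model="model1")
        assert res.estimate == pytest.approx(-0.8, abs=3 * res.se)
        assert res.p_value < 0.01 and res.covariates == []

    def test_model2_adjusts_confounder(self, rng):
        n = 500
        cov = _covariate_table(rng, n)
        score = 0.002 * (cov["energy_kcal"] - 2200) + rng.normal(size=n)
        y = 0.01 * cov["energy_kcal"] + rng.normal(0, 0.3, n)  # outcome driven by energy only
        res1 = d.outcome_regression(y, score, model="model1")
        res2 = d.outcome_regression(y, score, covariates=cov, model="model2")
        assert abs(res2.estimate) < abs(res1.estimate)
        assert set(["age", "energy_kcal", "pir", "bmi"]) <= set(res2.covariates)
        assert res2.notes  # records categorical reference levels

    def test_complete_case_counting(self, rng):
        n = 100
        score = rng.normal(size=n)
        y = score + rng.normal(size=n)
        y[:5] = np.nan
        res = d.outcome_regression(y, score, model="model1")
        assert res.n_used == 95

    def test_collinear_design_reported(self, rng):
        n = 80
        cov = _covariate_table(rng, n)
        cov["bmi"] = cov["age"] * 2.0  # exact collinearity within the design
        with pytest.raises(ValueError, match="collinear"):
            d.outcome_regression(rng.normal(size=n), rng.normal(size=n), covariates=cov, model="model2")

    def test_model2_requires_covariates(self, rng):
        with pytest.raises(ValueError):
            d.outcome_regression(rng.normal(size=50), rng.normal(size=50), model="model2")

    def test_adjusted_r2_not_above_r2(self, rng):
        n = 60
        score = rng.normal(size=n)
        y = 0.3 * score + rng.normal(size=n)
        res = d.outcome_regression(y, score, model="model1")
        r2 = np.corrcoef(y, score)[0, 1] ** 2
        assert res.adj_r2 <= r2 + 1e-12
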