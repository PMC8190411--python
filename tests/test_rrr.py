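"""Reduced-rank-regression core: standardization, factors, simplification."""

import numpy as np
import pandas as pd
import pytest

import dietrrr as d
from dietrrr.rrr import grid_search_max_explained


def _random_instance(seed, n=200, p=4, m=2, noise=1.0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.standard_normal((n, p)), columns=[f"x{i}" for i in range(p)])
    B = rng.standard_normal((p, m))
    Y = pd.DataFrame(X.to_numpy() @ B + noise * rng.standard_normal((n, m)), columns=["zn", "pufa"])
    Xs, _ = d.standardize_columns(X)
    Ys, _ = d.standardize_columns(Y)
    return Xs, Ys


class TestStandardize:
    def test_simple_column(self):
        z, params = d.standardize_columns(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(z["a"], [-1.0, 0.0, 1.0])
        assert params["sd"]["a"] == 1.0

    def test_idempotent(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=30)})
        z1, _ = d.standardize_columns(df)
        z2, _ = d.standardize_columns(z1)
        np.testing.assert_allclose(z1["a"], z2["a"], atol=1e-10)

    def test_constant_column_dropped_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            z, params = d.standardize_columns(df)
        assert list(z.columns) == ["a"] and params["dropped"] == ["b"]

    def test_all_constant_raises(self):
        with pytest.raises(ValueError):
            d.standardize_columns(pd.DataFrame({"a": [1.0, 1.0, 1.0]}))


class TestFitRRR:
    def test_response_inside_predictor_span(self, rng):
        X = pd.DataFrame(rng.standard_normal((50, 3)), columns=list("abc"))
        Xs, _ = d.standardize_columns(X)
        Y = pd.DataFrame({"zn": Xs["a"]})
        model = d.fit_rrr(Xs, Y, n_factors=1)
        assert model.explained["explained_zn"].iloc[0] == pytest.approx(1.0, abs=1e-10)
        assert model.loadings.loc["a", "factor1"] == pytest.approx(1.0, abs=1e-10)

    def test_orthonormal_closed_form(self):
        n = 64
        t = np.arange(n)
        x1 = np.cos(2 * np.pi * t / n) * np.sqrt(2)
        x2 = np.sin(2 * np.pi * t / n) * np.sqrt(2)
        X = pd.DataFrame({"x1": x1, "x2": x2})
        Y = pd.DataFrame({"zn": (x1 + x2) / np.sqrt(2), "pufa": (x1 - x2) / np.sqrt(2)})
        model = d.fit_rrr(X, Y, n_factors=2)
        assert model.explained["cumulative_overall"].iloc[-1] == pytest.approx(1.0, abs=1e-10)

    def test_factor1_matches_grid_search_oracle(self):
        Xs, Ys = _random_instance(123)
        model = d.fit_rrr(Xs, Ys, n_factors=2)
        grid = grid_search_max_explained(Xs, Ys, coarse_steps=30)
        assert model.explained["overall"].iloc[0] == pytest.approx(grid, abs=1e-3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_factor_scores_orthogonal_eigen_sorted_sign_fixed(self, seed):
        Xs, Ys = _random_instance(seed, n=150, p=6)
        model = d.fit_rrr(Xs, Ys, n_factors=2)
        F = model.factor_scores.to_numpy()
        assert abs(F[:, 0] @ F[:, 1]) < 1e-8 * len(F)
        assert model.eigenvalues[0] >= model.eigenvalues[1] >= 0
        for k in range(2):
            r = np.corrcoef(F[:, k], Ys["zn"])[0, 1]
            assert r >= -1e-12
        np.testing.assert_allclose(np.linalg.norm(model.response_weights, axis=0), 1.0, atol=1e-12)

    def test_projection_property(self):
        """corr(t_k, f_k)^2 equals the R^2 of regressing the response score on X."""
        Xs, Ys = _random_instance(7)
        model = d.fit_rrr(Xs, Ys, n_factors=2)
        Xv = Xs.to_numpy()
        for k in range(2):
            t = model.response_scores.iloc[:, k].to_numpy()
            f = model.factor_scores.iloc[:, k].to_numpy()
            beta, *_ = np.linalg.lstsq(np.column_stack([np.ones(len(t)), Xv]), t, rcond=None)
            fitted = np.column_stack([np.ones(len(t)), Xv]) @ beta
            r2 = 1 - ((t - fitted) ** 2).sum() / ((t - t.mean()) ** 2).sum()
            assert np.corrcoef(t, f)[0, 1] ** 2 == pytest.approx(r2, abs=1e-10)

    def test_too_many_factors_rejected(self):
        Xs, Ys = _random_instance(0)
        with pytest.raises(ValueError):
            d.fit_rrr(Xs, Ys, n_factors=3)

    def test_null_responses_explain_little(self):
        rng = np.random.default_rng(99)
        n = 2000
        X = pd.DataFrame(rng.standard_normal((n, 6)), columns=[f"x{i}" for i in range(6)])
        Y = pd.DataFrame(rng.standard_normal((n, 2)), columns=["zn", "pufa"])
        Xs, _ = d.standardize_columns(X)
        Ys, _ = d.standardize_columns(Y)
        model = d.fit_rrr(Xs, Ys, n_factors=2)
        assert (model.explained[["explained_zn", "explained_pufa"]].to_numpy() <= 0.05).all()


class TestLoadings:
    def test_match_direct_correlation(self):
        Xs, Ys = _random_instance(3, p=5)
        model = d.fit_rrr(Xs, Ys, n_factors=2)
        for k in range(2):
            f = model.factor_scores.iloc[:, k]
            for col in Xs.columns:
                assert model.loadings.loc[col, f"factor{k + 1}"] == pytest.approx(
                    np.corrcoef(Xs[col], f)[0, 1], abs=1e-12
                )

    def test_hand_explained_variation(self):
        Xs, Ys = _random_instance(11)
        model = d.fit_rrr(Xs, Ys, n_factors=1)
        f = model.factor_scores["factor1"]
        for j, resp in enumerate(["zn", "pufa"]):
            assert model.explained[f"explained_{resp}"].iloc[0] == pytest.approx(
                np.corrcoef(Ys[resp], f)[0, 1] ** 2, abs=1e-12
            )

    def test_projection_variant_available(self):
        Xs, Ys = _random_instance(5)
        model = d.fit_rrr(Xs, Ys, n_factors=1)
        proj = d.factor_loadings(model, Xs, kind="projection")
        f = model.factor_scores["factor1"].to_numpy()
        expected = Xs.to_numpy().T @ f / (f @ f)
        np.testing.assert_allclose(proj["factor1"], expected, atol=1e-12)


class TestSimplify:
    def _model_with_loadings(self, loadings):
        rng = np.random.default_rng(0)
        cols = [f"G{i + 1}" for i in range(len(loadings))]
        X = pd.DataFrame(rng.standard_normal((40, len(cols))), columns=cols)
        Xs, _ = d.standardize_columns(X)
        Y = pd.DataFrame({"zn": Xs.iloc[:, 0], "pufa": Xs.iloc[:, 1]})
        model = d.fit_rrr(Xs, Y, n_factors=1)
        model.loadings = pd.DataFrame({"factor1": loadings}, index=cols)
        return model, Xs

    def test_threshold_rule_by_hand(self):
        model, Xs = self._model_with_loadings([0.25, -0.30, 0.19, 0.05])
        pat = d.simplify_pattern(model, Xs, factor=1)
        assert pat.signs == {"G1": 1, "G2": -1}
        np.testing.assert_allclose(pat.score, Xs["G1"] - Xs["G2"])

    def test_boundary_loading_included(self):
        model, Xs = self._model_with_loadings([0.20, 0.10, -0.20, 0.0])
        pat = d.simplify_pattern(model, Xs, factor=1)
        assert pat.signs == {"G1": 1, "G3": -1}

    def test_empty_pattern_errors(self):
        model, Xs = self._model_with_loadings([0.1, -0.15, 0.05, 0.0])
        with pytest.raises(ValueError, match="empty simplified pattern"):
            d.simplify_pattern(model, Xs, factor=1)


class TestQuintiles:
    def test_even_split(self):
        q = d.assign_quintiles(np.arange(1.0, 11.0))
        np.testing.assert_array_equal(q, [1, 1, 2, 2, 3, 3, 4, 4, 5, 5])

    def test_sizes_differ_by_at_most_one(self):
        q = d.assign_quintiles(np.random.default_rng(1).normal(size=11))
        sizes = q.value_counts()
        assert sizes.max() - sizes.min() <= 1 and len(sizes) == 5

    def test_ties_stable_and_balanced(self):
        q = d.assign_quintiles(np.zeros(12))
        sizes = q.value_counts().sort_index()
        assert list(sizes) == [3, 3, 2, 2, 2]
        # stable rule: tied scores keep input order
        np.testing.assert_array_equal(q[:3], [1, 1, 1])

    def test_small_n_errors(self):
        with pytest.raises(ValueError):
            d.assign_quintiles([1.0, 2.0, 3.0, 4.0])
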