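"""Scaling, PCA, OPLS-DA/VIP, group tests and correlation matrices.

Oracles: PCA against a covariance eigendecomposition; OPLS-DA with no
orthogonal components against an independently written NIPALS PLS1 (and
scikit-learn's PLSRegression as a second cross-check); VIP closed forms for
symmetric and one-informative-variable designs.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plaquescope.multivariate import (
    compare_groups,
    encode_two_classes,
    oplsda,
    pca,
    pearson_matrix,
    scale_matrix,
    vip_scores,
)


def nipals_pls1(X, y, tol=1e-12, max_iter=500):
    """Independent single-component PLS1 reference (classic NIPALS loop)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = X.T @ y
    w /= np.linalg.norm(w)
    for _ in range(max_iter):
        t = X @ w
        c = (y @ t) / (t @ t)
        w_new = X.T @ y * c
        w_new /= np.linalg.norm(w_new)
        if np.linalg.norm(w_new - w) < tol:
            w = w_new
            break
        w = w_new
    t = X @ w
    p = X.T @ t / (t @ t)
    return w, t, p


class TestScaling:
    def test_autoscale_unit_sd_zero_mean(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5, 3, size=(20, 4))
        Xs, scaler = scale_matrix(X, "autoscale")
        np.testing.assert_allclose(Xs.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(Xs.std(axis=0, ddof=1), 1, atol=1e-9)

    def test_constant_column_flagged_and_zeroed(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 7.0)])
        Xs, scaler = scale_matrix(X, "autoscale")
        assert scaler.zero_variance.tolist() == [False, True]
        np.testing.assert_array_equal(Xs[:, 1], 0.0)

    def test_pareto_divides_by_sqrt_sd(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 50)
        x = (x - x.mean()) / x.std(ddof=1) * 4.0  # SD exactly 4
        Xs, _ = scale_matrix(x[:, None], "pareto")
        np.testing.assert_allclose(Xs[:, 0], (x - x.mean()) / 2.0, atol=1e-9)


class TestPca:
    def test_points_on_a_line_explained_by_pc1(self):
        t = np.linspace(-1, 1, 10)
        X = np.column_stack([t, 2 * t, -0.5 * t])
        _, _, expl = pca(X, 2)
        assert expl[0] == pytest.approx(1.0, abs=1e-9)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(2)
        Xs, _ = scale_matrix(rng.normal(size=(15, 6)))
        _, L, _ = pca(Xs, 4)
        np.testing.assert_allclose(L.T @ L, np.eye(4), atol=1e-9)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        Xs, _ = scale_matrix(rng.normal(size=(6, 4)))
        scores, loadings, expl = pca(Xs, 3)
        cov = np.cov(Xs, rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for j in range(3):
            v = evecs[:, j]
            sign = np.sign(v @ loadings[:, j]) or 1.0
            np.testing.assert_allclose(loadings[:, j], sign * v, atol=1e-8)
        np.testing.assert_allclose(expl, evals[:3] / evals.sum(), atol=1e-8)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(4)
        Xs, _ = scale_matrix(rng.normal(size=(8, 5)))
        scores, loadings, _ = pca(Xs, 5)
        np.testing.assert_allclose(scores @ loadings.T, Xs, atol=1e-8)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            pca(np.zeros((4, 10)), 4)


class TestOplsda:
    def test_noiseless_separable_single_direction(self):
        y = np.array(["a"] * 5 + ["b"] * 5)
        signal = np.array([-1.0] * 5 + [1.0] * 5)
        X = np.column_stack([signal, np.zeros(10), np.zeros(10)])
        model = oplsda(X, y, n_orth=0, scaling="center_only")
        w = model.weights
        assert abs(w[0]) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(w[1:], 0.0, atol=1e-12)
        t = model.scores
        # perfect class separation by score sign
        assert len(set(np.sign(t[:5]))) == 1
        assert len(set(np.sign(t[5:]))) == 1
        assert np.sign(t[0]) == -np.sign(t[5])

    def test_equals_nipals_pls1_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(14, 8))
        y = np.array(["a", "b"] * 7)
        model = oplsda(X, y, n_orth=0)
        Xs, _ = scale_matrix(X)
        y_enc, _ = encode_two_classes(y)
        w_ref, t_ref, p_ref = nipals_pls1(Xs, y_enc - y_enc.mean())
        sign = np.sign(w_ref @ model.weights)
        np.testing.assert_allclose(model.weights, sign * w_ref, atol=1e-8)
        np.testing.assert_allclose(model.scores, sign * t_ref, atol=1e-8)
        np.testing.assert_allclose(model.loadings, sign * p_ref, atol=1e-8)

    def test_matches_sklearn_pls_direction(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(6)
        X = rng.normal(size=(12, 5))
        y = np.array(["a"] * 6 + ["b"] * 6)
        model = oplsda(X, y, n_orth=0)
        y_enc, _ = encode_two_classes(y)
        Xs, _ = scale_matrix(X)
        ref = PLSRegression(n_components=1, scale=False).fit(Xs, y_enc)
        w_ref = ref.x_weights_[:, 0]
        sign = np.sign(w_ref @ model.weights)
        np.testing.assert_allclose(model.weights, sign * w_ref, atol=1e-8)

    def test_orthogonal_component_removes_confounder(self):
        # planted predictive direction + strong y-orthogonal confounder
        rng = np.random.default_rng(7)
        n, p = 24, 10
        y = np.array(["a"] * 12 + ["b"] * 12)
        y_enc, _ = encode_two_classes(y)
        beta = np.zeros(p)
        beta[0] = 1.0
        conf_dir = np.zeros(p)
        conf_dir[1:4] = [3.0, -2.0, 1.5]
        conf = rng.normal(size=n)  # nominally y-orthogonal structured noise
        X = (np.outer(y_enc, beta) + np.outer(conf, conf_dir)
             + 0.05 * rng.normal(size=(n, p)))
        m0 = oplsda(X, y, n_orth=0, scaling="center_only")
        m1 = oplsda(X, y, n_orth=1, scaling="center_only")

        def align(model):
            # correlation of the predictive loading with the planted direction
            return abs(model.loadings[0]) / np.linalg.norm(model.loadings)

        assert align(m1) > align(m0)

    def test_predictive_scores_orthogonal_to_orthogonal_scores(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(16, 7))
        y = np.array(["a", "b"] * 8)
        model = oplsda(X, y, n_orth=2)
        for j in range(model.orth_scores.shape[1]):
            assert abs(model.scores @ model.orth_scores[:, j]) < 1e-8

    def test_r2y_non_decreasing_in_n_orth(self):
        from plaquescope.multivariate import r2y

        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 12))
        y = np.array(["a"] * 10 + ["b"] * 10)
        r2 = [r2y(oplsda(X, y, n_orth=k), X, y) for k in (0, 1, 2)]
        assert r2[0] <= r2[1] + 1e-12 <= r2[2] + 2e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            oplsda(np.random.default_rng(0).normal(size=(6, 3)), ["a"] * 6)


class TestVip:
    def test_equal_weights_give_unit_vip(self):
        y = np.array(["a", "a", "b", "b"])
        base = np.array([-1.0, -1, 1, 1])
        X = np.column_stack([base, base, base, base])
        model = oplsda(X, y, n_orth=0, scaling="center_only")
        vip, _ = vip_scores(model)
        np.testing.assert_allclose(vip, 1.0, atol=1e-9)

    def test_single_informative_variable_closed_form(self):
        p = 6
        y = np.array(["a"] * 4 + ["b"] * 4)
        X = np.zeros((8, p))
        X[:, 2] = [-1, -1, -1, -1, 1, 1, 1, 1]
        model = oplsda(X, y, n_orth=0, scaling="center_only")
        vip, ranking = vip_scores(model)
        assert vip[2] == pytest.approx(np.sqrt(p), abs=1e-9)
        np.testing.assert_allclose(np.delete(vip, 2), 0.0, atol=1e-9)
        assert ranking[0] == 2

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_mean_squared_vip_is_one(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 16))
        p = int(rng.integers(2, 12))
        X = rng.normal(size=(n, p))
        y = np.array(["a", "b"] * ((n + 1) // 2))[:n]
        if len(set(y)) < 2:
            return
        model = oplsda(X, y, n_orth=int(rng.integers(0, 3)))
        vip, _ = vip_scores(model)
        assert np.mean(vip**2) == pytest.approx(1.0, abs=1e-8)


class TestCompareGroups:
    def test_identical_groups_give_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labels = ["a"] * 3 + ["b"] * 3
        res = compare_groups(pd.DataFrame({"v": x}), labels)
        assert res.loc["v", "t"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc["v", "p"] == pytest.approx(1.0, abs=1e-12)

    def test_large_effect_significant_after_bh(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0, 0.1, 5)
        b = rng.normal(10, 0.1, 5)
        X = pd.DataFrame({"v": np.concatenate([a, b]),
                          "noise": rng.normal(size=10)})
        res = compare_groups(X, ["a"] * 5 + ["b"] * 5)
        assert res.loc["v", "q"] < 1e-3
        assert res.loc["v", "effect"] == pytest.approx(10.0, abs=0.2)

    def test_permutation_type_i_error_calibrated(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=20)
        hits = 0
        n_perm = 1000
        for _ in range(n_perm):
            labels = rng.permutation(["a"] * 10 + ["b"] * 10)
            res = compare_groups(pd.DataFrame({"v": x}), labels)
            hits += res.loc["v", "p"] < 0.05
        assert hits / n_perm <= 0.07

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(pd.DataFrame({"v": [1.0, 2, 3]}), ["a", "b", "b"])


class TestPearsonMatrix:
    def test_self_and_anti_correlation(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        corr, _ = pearson_matrix(pd.DataFrame({"x": x, "mx": -x}))
        assert corr.loc["x", "x"] == 1.0
        assert corr.loc["x", "mx"] == pytest.approx(-1.0)

    def test_three_point_closed_form(self):
        # r = cov / (sd_x sd_y) for x=(1,2,3), y=(1,2,4): r = 0.981980...
        corr, _ = pearson_matrix(pd.DataFrame({"x": [1.0, 2, 3],
                                               "y": [1.0, 2, 4]}))
        assert corr.loc["x", "y"] == pytest.approx(0.9819805, abs=1e-6)

    def test_symmetric_unit_diagonal_bounded(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(rng.normal(size=(9, 5)))
        corr, _ = pearson_matrix(df)
        np.testing.assert_allclose(corr.values, corr.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(corr.values), 1.0, atol=1e-12)
        assert (corr.values <= 1 + 1e-12).all() and (corr.values >= -1 - 1e-12).all()

    def test_row_shuffle_invariance(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame(rng.normal(size=(8, 4)))
        perm = rng.permutation(8)
        corr1, _ = pearson_matrix(df)
        corr2, _ = pearson_matrix(df.iloc[perm])
        np.testing.assert_allclose(corr1.values, corr2.values, atol=1e-12)

    def test_zero_variance_column_excluded_and_reported(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "const": [5.0] * 4})
        corr, meta = pearson_matrix(df)
        assert "const" not in corr.columns
        assert "const" in meta["excluded_zero_variance"].tolist()

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            pearson_matrix(pd.DataFrame({"x": [1.0, 2]}))
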