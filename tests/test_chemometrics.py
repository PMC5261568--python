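"""PCA, confidence ellipses, NIPALS PLS1, LOOCV, thresholds, accuracy."""

import numpy as np
import pytest
from scipy.stats import chi2

from ftirmark import (SpectrumSet, ThresholdRule, accuracy_table,
                      classify_y, confidence_ellipse, pca_fit, pls1_fit,
                      pls_loocv)


class TestPCA:
    def test_rank_one_data_explains_everything(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(6)
        X = np.outer(rng.standard_normal(10), base)
        model = pca_fit(X, 1)
        assert model.explained_variance_pct[0] == pytest.approx(100.0)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((8, 5))
        model = pca_fit(X, 5)
        recon = model.scores @ model.loadings
        assert np.linalg.norm(X - X.mean(axis=0) - recon) < 1e-9

    def test_matches_covariance_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((5, 4))
        model = pca_fit(X, 3)
        cov = np.cov(X, rowvar=False, ddof=1)
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1]
        eigvecs = eigvecs[:, order]
        for k in range(3):
            dot = abs(model.loadings[k] @ eigvecs[:, k])
            assert dot == pytest.approx(1.0, abs=1e-9)
        # variance fractions agree with the eigenvalue ratios
        expected = 100 * eigvals[order] / eigvals.sum()
        np.testing.assert_allclose(model.explained_variance_pct,
                                   expected[:3], atol=1e-9)

    def test_matches_sklearn(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(3)
        X = rng.standard_normal((20, 7))
        model = pca_fit(X, 4)
        ref = sklearn.PCA(n_components=4).fit(X)
        for k in range(4):
            assert abs(model.loadings[k] @ ref.components_[k]) == \
                pytest.approx(1.0, abs=1e-9)

    def test_loading_sign_convention(self, preprocessed):
        windowed, _ = preprocessed
        pca_set = windowed.select_split("pca_cal")
        model = pca_fit(pca_set, 8)
        nu = pca_set.wavenumbers
        ch1621 = np.argmin(np.abs(nu - 1621))
        ch1650 = np.argmin(np.abs(nu - 1650))
        assert model.loadings[0, ch1621] > 0
        assert model.loadings[0, ch1650] < 0

    def test_pc1_sign_separates_classes(self, preprocessed):
        """Electrical-mark and normal-epidermis scores occupy opposite
        PC1 half-axes with no overlap on the default calibration set."""
        windowed, _ = preprocessed
        pca_set = windowed.select_split("pca_cal")
        model = pca_fit(pca_set, 8)
        s_ele = model.scores[pca_set.labels == "electrical_mark", 0]
        s_epi = model.scores[pca_set.labels == "normal_epidermis", 0]
        assert np.ptp(np.sign(s_ele)) == 0 and np.ptp(np.sign(s_epi)) == 0
        assert np.sign(s_ele[0]) != np.sign(s_epi[0])

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            pca_fit(np.zeros((4, 10)), 4)


class TestConfidenceEllipse:
    @staticmethod
    def _whitened(n, rng):
        pts = rng.standard_normal((n, 2))
        pts -= pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False)
        L = np.linalg.cholesky(np.linalg.inv(cov))
        return pts @ L  # exact unit sample covariance

    def test_isotropic_unit_variance_axes(self):
        pts = self._whitened(50, np.random.default_rng(0))
        ell = confidence_ellipse(pts, 0.95)
        expected = np.sqrt(chi2.ppf(0.95, 2))
        np.testing.assert_allclose(ell.semi_axes, expected, rtol=1e-9)

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(1)
        pts = rng.standard_normal((40, 2)) @ np.array([[2.0, 0.3],
                                                       [0.0, 0.7]])
        e1 = confidence_ellipse(pts, 0.95)
        e2 = confidence_ellipse(2.0 * pts, 0.95)
        np.testing.assert_allclose(e2.semi_axes, 2.0 * e1.semi_axes,
                                   rtol=1e-9)

    def test_monte_carlo_coverage(self):
        rng = np.random.default_rng(7)
        pts = rng.multivariate_normal([1.0, -2.0],
                                      [[2.0, 0.8], [0.8, 1.0]], size=5000)
        ell = confidence_ellipse(pts, 0.95)
        coverage = ell.contains(pts).mean()
        assert coverage == pytest.approx(0.95, abs=0.02)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            confidence_ellipse(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            confidence_ellipse(np.tile([1.0, 2.0], (10, 1)))


class TestPLS1:
    def test_single_varying_channel_exact_with_one_factor(self):
        rng = np.random.default_rng(0)
        X = np.tile([0.5, -0.2, 1.0, 0.0], (12, 1))
        X[:, 2] = rng.standard_normal(12)
        y = 3.0 * X[:, 2] + 1.0
        model = pls1_fit(X, y, 1)
        np.testing.assert_allclose(model.predict(X), y, atol=1e-8)

    def test_full_rank_equals_least_squares(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((8, 5))
        y = rng.standard_normal(8)
        model = pls1_fit(X, y, 5)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        b_ols = np.linalg.solve(Xc.T @ Xc, Xc.T @ yc)
        np.testing.assert_allclose(model.coef, b_ols, atol=1e-8)

    def test_training_mean_predicts_y_mean(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((10, 6))
        y = rng.standard_normal(10)
        model = pls1_fit(X, y, 3)
        assert model.predict(X.mean(axis=0)[None, :])[0] == \
            pytest.approx(y.mean(), abs=1e-12)

    def test_first_weight_proportional_to_xty(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((15, 8))
        y = rng.standard_normal(15)
        model = pls1_fit(X, y, 1)
        w = (X - X.mean(axis=0)).T @ (y - y.mean())
        cosine = model.coef @ w / (np.linalg.norm(model.coef)
                                   * np.linalg.norm(w))
        assert abs(cosine) == pytest.approx(1.0, abs=1e-10)

    def test_matches_sklearn_predictions(self):
        PLSRegression = pytest.importorskip(
            "sklearn.cross_decomposition").PLSRegression
        rng = np.random.default_rng(4)
        X = rng.standard_normal((25, 10))
        y = X @ rng.standard_normal(10) + 0.1 * rng.standard_normal(25)
        for k in (1, 2, 4):
            mine = pls1_fit(X, y, k).predict(X)
            ref = PLSRegression(n_components=k, scale=False).fit(
                X, y).predict(X).ravel()
            np.testing.assert_allclose(mine, ref, atol=1e-8)

    def test_zero_variance_y_rejected(self):
        with pytest.raises(ValueError):
            pls1_fit(np.random.default_rng(0).standard_normal((5, 3)),
                     np.ones(5), 1)

    def test_rank_deficient_deflation_rejected(self):
        rng = np.random.default_rng(5)
        base = rng.standard_normal(6)
        X = np.outer(rng.standard_normal(8), base)  # rank 1 after centering
        y = X[:, 0] + 1.0
        with pytest.raises(ValueError, match="degenerate"):
            pls1_fit(X, y, 4)

    def test_grid_mismatch_on_predict_rejected(self, preprocessed,
                                               trained_pls):
        windowed, _ = preprocessed
        model, _ = trained_pls
        other = SpectrumSet(windowed.wavenumbers[:-1],
                            windowed.values[:1, :-1])
        with pytest.raises(ValueError, match="grid"):
            model.predict(other)


class TestLOOCV:
    def test_noiseless_rank_two_structure(self):
        rng = np.random.default_rng(0)
        T = rng.standard_normal((20, 2))
        P = rng.standard_normal((2, 9))
        X = T @ P
        y = T @ np.array([1.5, -0.5]) + 2.0
        cv = pls_loocv(X, y, max_factors=6)
        assert cv.chosen <= 2
        assert cv.rmsecv[1] < 1e-8

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((15, 6))
        y = X @ rng.standard_normal(6) + 0.2 * rng.standard_normal(15)
        cv = pls_loocv(X, y, max_factors=4)
        perm = rng.permutation(15)
        cv_p = pls_loocv(X[perm], y[perm], max_factors=4)
        np.testing.assert_allclose(cv_p.rmsecv, cv.rmsecv, atol=1e-10)
        np.testing.assert_allclose(cv_p.predictions, cv.predictions[perm],
                                   atol=1e-10)

    def test_duplicated_samples_flatten_rmsecv(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((8, 4))
        y = X @ rng.standard_normal(4)
        X2, y2 = np.vstack([X, X]), np.concatenate([y, y])
        cv = pls_loocv(X2, y2, max_factors=4)
        assert np.all(np.diff(cv.rmsecv) < 1e-8)  # non-increasing then flat

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError):
            pls_loocv(np.random.default_rng(0).standard_normal((6, 3)),
                      np.full(6, 2.0), 2)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pls_loocv(np.zeros((2, 3)), np.array([1.0, 2.0]), 1)


class TestThresholds:
    @pytest.mark.parametrize("y,expected", [
        (1.0, "normal_epidermis"),
        (2.0, "electrical_mark"),
        (3.0, "normal_dermis"),
        (1.5, "electrical_mark"),      # closed electrical interval
        (2.5, "electrical_mark"),
        (2.5000001, "normal_dermis"),
        (1.4999999, "normal_epidermis"),
        (-5.0, "normal_epidermis"),
    ])
    def test_boundary_conventions(self, y, expected):
        assert classify_y(np.array([y]))[0] == expected

    def test_every_y_maps_to_exactly_one_class(self):
        y = np.linspace(-2, 6, 4001)
        labels = classify_y(y)
        assert not any(l is None for l in labels)

    def test_unordered_boundaries_rejected(self):
        with pytest.raises(ValueError):
            ThresholdRule(lower=2.5, upper=1.5)


class TestAccuracyTable:
    def test_table_matches_hand_counts(self):
        true = ["normal_epidermis"] * 20 + ["normal_dermis"] * 14
        pred = (["normal_epidermis"] * 17 + ["electrical_mark"] * 3
                + ["normal_dermis"] * 11 + ["normal_epidermis"] * 3)
        table = accuracy_table(pred, true).set_index("class")
        epi = table.loc["normal_epidermis"]
        assert (epi["correct"], epi["false"]) == (17, 3)
        assert epi["accuracy_pct"] == 85.0
        der = table.loc["normal_dermis"]
        assert (der["correct"], der["false"]) == (11, 3)
        assert der["accuracy_pct"] == 78.6

    def test_all_correct(self):
        labels = ["electrical_mark"] * 5
        table = accuracy_table(labels, labels)
        assert table["accuracy_pct"].iloc[0] == 100.0

    def test_y_range_column(self):
        labels = ["normal_epidermis", "electrical_mark", "normal_dermis"]
        table = accuracy_table(labels, labels)
        assert list(table["y_range"]) == ["0–1.5", "1.5–2.5", ">2.5"]

    def test_disjoint_label_sets_rejected(self):
        with pytest.raises(ValueError):
            accuracy_table(["a", "b"], ["c", "d"])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            accuracy_table(["normal_dermis"], ["normal_dermis"] * 2)
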