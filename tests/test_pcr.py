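"""PCR signature training: residualization, 1-SE selection, LOSO, Haufe."""

import numpy as np
import pytest

from connsig.pcr import (
    CovariateResidualizer,
    PCRSignature,
    build_signature,
    default_component_grid,
    haufe_transform,
    loso_cv,
    one_se_choice,
)


class TestResidualizer:
    def test_intercept_only_mean_centers(self, rng):
        y = rng.normal(size=50)
        out = CovariateResidualizer().fit_transform(np.empty((50, 0)), y)
        assert np.allclose(out, y - y.mean(), atol=1e-12)

    def test_target_equal_to_covariate_vanishes(self, rng):
        c = rng.normal(size=(60, 1))
        out = CovariateResidualizer().fit_transform(c, c[:, 0])
        assert np.max(np.abs(out)) < 1e-10

    def test_residuals_orthogonal_to_covariates(self, rng):
        C = rng.normal(size=(100, 3))
        y = rng.normal(size=100) + C @ [1.0, -2.0, 0.5]
        out = CovariateResidualizer().fit_transform(C, y)
        for j in range(3):
            assert abs(np.corrcoef(out, C[:, j])[0, 1]) < 1e-10

    def test_heldout_rows_use_training_coefficients(self, rng):
        # train and test covariate means differ; joint residualization leaks
        c_train = rng.normal(0.0, 1.0, size=(80, 1))
        c_test = rng.normal(5.0, 1.0, size=(20, 1))
        beta = 2.0
        y_train = beta * c_train[:, 0] + rng.normal(size=80)
        y_test = beta * c_test[:, 0] + rng.normal(size=20)
        res = CovariateResidualizer().fit(c_train, y_train)
        proper = res.transform(c_test, y_test)
        joint = CovariateResidualizer().fit_transform(
            np.vstack([c_train, c_test]), np.concatenate([y_train, y_test])
        )[80:]
        assert not np.allclose(proper, joint, atol=1e-3)
        # proper residuals stay centered near zero despite the mean shift
        assert abs(proper.mean()) < 1.0

    def test_collinear_columns_named(self, rng):
        c = rng.normal(size=(40, 1))
        C = np.column_stack([c, 2 * c])
        with pytest.raises(ValueError, match="collinear"):
            CovariateResidualizer().fit(C, rng.normal(size=40))


class TestComponentSelection:
    def test_flat_curve_picks_smallest(self):
        assert one_se_choice([3.0, 3.0, 3.0], [0.1, 0.1, 0.1], [1, 4, 8]) == 1

    def test_decreasing_curve_tiny_se_picks_argmin(self):
        assert one_se_choice([5, 4, 3, 2], [1e-9] * 4, [1, 2, 4, 8]) == 8

    def test_one_se_rule_by_hand(self):
        # min at last (4.85, SE 0.2); 5 <= 4.85+0.2 -> second grid value
        assert one_se_choice([10, 5, 4.9, 4.85], [0.5, 0.3, 0.25, 0.2], [1, 2, 4, 8]) == 2

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            one_se_choice([], [], [])

    def test_default_grid_capped_and_contains_parity_k(self):
        grid = default_component_grid(600)
        assert max(grid) <= 60 and 21 in grid and grid[0] == 1


class TestPCRSignature:
    def test_full_rank_pcr_equals_ols(self, rng):
        X = rng.normal(size=(40, 20))
        y = X @ rng.normal(size=20) + rng.normal(size=40)
        model = PCRSignature(n_components=20).fit(X, y)
        D = np.column_stack([np.ones(40), X])
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        assert np.allclose(model.predict(X), D @ beta, atol=1e-8)

    def test_y_orthogonal_to_components_gives_zero_betas(self, rng):
        X = rng.normal(size=(30, 10))
        Xc = X - X.mean(axis=0)
        # y in the orthogonal complement of the column space of Xc
        q, _ = np.linalg.qr(Xc)
        y = rng.normal(size=30)
        y -= q @ (q.T @ y)
        model = PCRSignature(n_components=5).fit(X, y)
        assert np.max(np.abs(model.betas_)) < 1e-10

    def test_duplicating_subjects_leaves_map_unchanged(self, rng):
        X = rng.normal(size=(35, 15))
        y = rng.normal(size=35)
        m1 = PCRSignature(n_components=6).fit(X, y)
        m2 = PCRSignature(n_components=6).fit(np.vstack([X, X]), np.concatenate([y, y]))
        assert np.allclose(m1.weights_, m2.weights_, atol=1e-8)

    def test_mean_connectome_predicts_mean_score(self, rng):
        X = rng.normal(size=(50, 12))
        y = rng.normal(size=50)
        m = PCRSignature(n_components=4).fit(X, y)
        assert m.predict(X.mean(axis=0)[None, :])[0] == pytest.approx(y.mean(), abs=1e-10)

    def test_requesting_more_components_than_rank_fails(self, rng):
        X = rng.normal(size=(10, 30))
        with pytest.raises(ValueError, match="rank"):
            PCRSignature(n_components=15).fit(X, rng.normal(size=10))


class TestHaufe:
    def test_pattern_equals_brute_force_edge_covariance(self, rng):
        X = rng.normal(size=(60, 25))
        w = rng.normal(size=25)
        yhat = X @ w
        pattern = haufe_transform(X, w)
        var = np.var(yhat, ddof=1)
        for e in range(25):
            cov_e = np.cov(X[:, e], yhat, ddof=1)[0, 1]
            assert pattern[e] == pytest.approx(cov_e / var, abs=1e-10)

    def test_whitened_features_leave_weights_proportional(self, rng):
        # exactly whiten the sample covariance
        X = rng.normal(size=(200, 8))
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / 199
        X_w = Xc @ np.linalg.inv(np.linalg.cholesky(cov)).T
        w = rng.normal(size=8)
        pattern = haufe_transform(X_w, w)
        assert np.allclose(pattern / np.linalg.norm(pattern),
                           w / np.linalg.norm(w), atol=1e-8)

    def test_zero_variance_prediction_rejected(self, rng):
        X = rng.normal(size=(20, 5))
        with pytest.raises(ValueError):
            haufe_transform(X, np.zeros(5))


class TestLOSO:
    def test_needs_three_sites(self, rng):
        X = rng.normal(size=(20, 6))
        with pytest.raises(ValueError):
            loso_cv(X, rng.normal(size=20), np.repeat(["a", "b"], 10))

    def test_pure_noise_r_cv_near_zero(self, rng):
        n, sites = 180, np.repeat(np.arange(6), 30)
        X = rng.normal(size=(n, 40))
        y = rng.normal(size=n)
        cv = loso_cv(X, y, sites, grid=[1, 2, 4], random_state=0)
        assert abs(cv.mean_r) < 2.5 / np.sqrt(30)

    def test_identical_connectomes_flagged_nan(self, rng):
        n, sites = 30, np.repeat(np.arange(3), 10)
        X = np.ones((n, 8))
        y = rng.normal(size=n)
        with pytest.warns(RuntimeWarning):
            cv = loso_cv(X, y, sites, grid=[1])
        assert np.isnan(list(cv.per_site_r.values())).all()


class TestBuildSignature:
    def test_single_component_weights_follow_first_pc(self, rng):
        X = rng.normal(size=(40, 10))
        y = rng.normal(size=40)
        sig = build_signature(X, y, n_components=1)
        Xc = X - X.mean(axis=0)
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        cos = abs(sig.weights @ vt[0]) / np.linalg.norm(sig.weights)
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_weight_path_equals_component_path(self, rng):
        X = rng.normal(size=(50, 14))
        y = rng.normal(size=50)
        m = PCRSignature(n_components=5).fit(X, y)
        Xnew = rng.normal(size=(50, 14))
        via_weights = m.predict(Xnew)
        scores = (Xnew - m.mean_) @ m.components_.T
        via_components = scores @ m.betas_ + m.y_mean_
        assert np.allclose(via_weights, via_components, atol=1e-10)
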