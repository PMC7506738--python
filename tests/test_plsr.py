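"""NIPALS PLS1: factor extraction, CV, diagnostics, outliers, jack-knife."""

import warnings

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from anthonir.plsr import (
    NIPALSPLSRegression,
    compute_metrics,
    fit_plsr,
    hotelling_outliers,
    load_model,
    loo_cv,
    save_model,
    select_n_factors,
    significant_regions,
    uncertainty_test,
)


class TestFit:
    def test_single_latent_variable(self, rng):
        t = rng.normal(size=12)
        p = rng.normal(size=8)
        X = np.outer(t, p)
        y = 2.0 * t
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_plsr(X, y, n_factors=3)
        assert m.n_components_ == 1  # rank exhausted after one factor
        rmsec = np.sqrt(np.mean((m.predict(X) - y) ** 2))
        assert rmsec <= 1e-10 * y.std()

    def test_full_rank_equals_ols(self, rng):
        # at full rank PLS spans the same column space as OLS
        X = rng.normal(size=(6, 4))
        y = rng.normal(size=6)
        m = fit_plsr(X, y, n_factors=4)
        Xc = X - X.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
        expected = y.mean() + Xc @ beta
        assert np.allclose(m.predict(X), expected, rtol=1e-8, atol=1e-10)

    def test_matches_independent_pls_implementation(self, rng):
        X = rng.normal(size=(8, 5))
        y = rng.normal(size=8)
        ours = fit_plsr(X, y, n_factors=2)
        ref = PLSRegression(n_components=2, scale=False).fit(X, y)
        b_ref = ref.coef_.ravel()
        assert np.allclose(ours.coef_, b_ref, rtol=1e-6)

    def test_score_orthogonality(self, rng):
        X = rng.normal(size=(15, 40))
        y = X[:, 0] + rng.normal(size=15)
        m = fit_plsr(X, y, n_factors=5)
        G = m.x_scores_.T @ m.x_scores_
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(G))

    def test_coef_reproduces_fitted_values(self, rng):
        X = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        m = fit_plsr(X, y, n_factors=3)
        manual = m.y_mean_ + (X - m.x_mean_) @ m.coef_
        assert np.array_equal(m.predict(X), manual)

    def test_zero_variance_y_errors(self, rng):
        X = rng.normal(size=(5, 3))
        with pytest.raises(ValueError, match="variance"):
            fit_plsr(X, np.ones(5), n_factors=1)

    def test_excess_factors_warn_and_record(self, rng):
        t = rng.normal(size=10)
        X = np.outer(t, rng.normal(size=6))
        with pytest.warns(UserWarning, match="rank"):
            m = fit_plsr(X, 3 * t, n_factors=4)
        assert m.n_components_ == 1


class TestPredict:
    def test_mean_row_predicts_mean(self, rng):
        X = rng.normal(size=(9, 5))
        y = rng.normal(size=9)
        m = fit_plsr(X, y, n_factors=2)
        assert np.allclose(m.predict(m.x_mean_[None, :]), m.y_mean_)

    def test_held_out_manual_dot_product(self, rng):
        X = rng.normal(size=(9, 5))
        y = rng.normal(size=9)
        m = fit_plsr(X, y, n_factors=2)
        x_new = rng.normal(size=5)
        assert np.isclose(
            m.predict(x_new)[0], m.y_mean_ + (x_new - m.x_mean_) @ m.coef_
        )

    def test_grid_mismatch_errors(self, rng):
        m = fit_plsr(rng.normal(size=(6, 5)), rng.normal(size=6), 2)
        with pytest.raises(ValueError, match="grid mismatch"):
            m.predict(np.zeros((1, 4)))


class TestLooCV:
    def test_constant_y_gives_zero_rmsecv(self, rng):
        X = rng.normal(size=(6, 4))
        res = loo_cv(X, np.full(6, 7.0), max_factors=2)
        assert np.allclose(res.rmsecv, 0.0)

    def test_noise_free_single_latent(self, rng):
        t = rng.normal(size=10)
        X = np.outer(t, rng.normal(size=20))
        y = 5.0 * t
        res = loo_cv(X, y, max_factors=2)
        assert res.rmsecv[0] <= 1e-8 * y.std()

    def test_matches_explicit_fold_loop(self, rng):
        X = rng.normal(size=(7, 4))
        y = rng.normal(size=7)
        res = loo_cv(X, y, max_factors=2)
        # written-out leave-one-out loop as the independent oracle
        for k in (1, 2):
            errs = []
            for i in range(7):
                keep = np.arange(7) != i
                m = NIPALSPLSRegression(n_components=k).fit(X[keep], y[keep])
                errs.append(y[i] - m.predict(X[i])[0])
            assert np.isclose(res.rmsecv[k - 1], np.sqrt(np.mean(np.square(errs))))

    def test_parsimony_rule(self):
        assert select_n_factors(np.array([10.0, 4.95, 4.92, 4.90])) == 2
        assert select_n_factors(np.array([10.0, 9.0, 3.0])) == 3


class TestMetrics:
    def test_rsd_definition(self):
        y = np.array([50.0, 100.0, 150.0])  # mean 100
        yhat_cv = y + np.array([10.0, -10.0, 10.0])  # RMSECV 10
        m = compute_metrics(y, y, yhat_cv, n_factors=1)
        assert np.isclose(m.rmsecv, 10.0)
        assert np.isclose(m.rsd_plsr_percent, 10.0)

    def test_perfect_cv(self, rng):
        y = rng.normal(size=8)
        m = compute_metrics(y, y, y, n_factors=2)
        assert m.rmsecv == 0.0 and m.r2_val == 1.0 and m.ratio == 0.0

    def test_sums_of_squares_oracle(self, rng):
        y = rng.normal(loc=10, size=12)
        e_cal = rng.normal(scale=0.5, size=12)
        e_cv = rng.normal(scale=0.8, size=12)
        m = compute_metrics(y, y + e_cal, y + e_cv, n_factors=3)
        sst = np.sum((y - y.mean()) ** 2)
        assert np.isclose(m.rmsec, np.sqrt(np.mean(e_cal**2)))
        assert np.isclose(m.r2_cal, 1 - np.sum(e_cal**2) / sst)
        assert np.isclose(m.r2_val, 1 - np.sum(e_cv**2) / sst)
        assert np.isclose(m.ratio, m.rmsecv / m.rmsec)

    def test_midrange_denominator_option(self):
        y = np.array([0.0, 10.0, 100.0])
        # avoid zero-variance residual corner: inject simple errors
        m = compute_metrics(y, y, y + 5.0, 1, rsd_denominator="midrange")
        assert np.isclose(m.rsd_plsr_percent, 100 * 5.0 / 50.0)


class TestHotelling:
    def test_zero_scores_no_flags(self, rng):
        m = fit_plsr(rng.normal(size=(8, 4)), rng.normal(size=8), 2)
        m.x_scores_ = np.zeros_like(m.x_scores_)  # all samples identical
        res = hotelling_outliers(m)
        assert np.allclose(res.t2, 0.0) and not res.flags.any()

    def test_equals_mahalanobis_oracle(self, rng):
        X = rng.normal(size=(20, 10))
        y = X[:, :3] @ np.array([1.0, -2.0, 0.5]) + rng.normal(size=20)
        m = fit_plsr(X, y, 3)
        res = hotelling_outliers(m)
        T = m.x_scores_
        cov = np.cov(T, rowvar=False)
        d2 = np.array(
            [tc @ np.linalg.solve(cov, tc) for tc in (T - T.mean(axis=0))]
        )
        # scores are centered and orthogonal, so T^2 == Mahalanobis distance
        assert np.allclose(res.t2, d2, rtol=1e-6)

    def test_displaced_sample_flagged(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(20, 30))
        y = X[:, 0] + 0.1 * rng.normal(size=20)
        m0 = fit_plsr(X, y, 2)
        sd1 = m0.x_scores_[:, 0].std(ddof=1)
        X2 = X.copy()
        X2[7] = X[7] + 10.0 * sd1 * m0.x_weights_[:, 0]
        m = fit_plsr(X2, y, 2)
        res = hotelling_outliers(m, alpha=0.05)
        assert res.flags[7]
        assert np.flatnonzero(res.flags).tolist() == [7]

    def test_removing_outlier_never_increases_rmsec(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(18, 25))
        y = X[:, 0] + 0.05 * rng.normal(size=18)
        m0 = fit_plsr(X, y, 2)
        X2 = X.copy()
        X2[3] += 10.0 * m0.x_scores_[:, 0].std(ddof=1) * m0.x_weights_[:, 0]
        m_all = fit_plsr(X2, y, 2)
        rmsec_all = np.sqrt(np.mean((m_all.predict(X2) - y) ** 2))
        flags = hotelling_outliers(m_all).flags
        keep = ~flags
        m_rm = fit_plsr(X2[keep], y[keep], 2)
        rmsec_rm = np.sqrt(np.mean((m_rm.predict(X2[keep]) - y[keep]) ** 2))
        assert flags[3]
        assert rmsec_rm <= rmsec_all + 1e-12

    def test_as_many_factors_as_samples_errors(self, rng):
        m = fit_plsr(rng.normal(size=(4, 10)), rng.normal(size=4), 3)
        m.x_scores_ = m.x_scores_[:3, :]  # k == n: F limit undefined
        with pytest.raises(ValueError):
            hotelling_outliers(m)


class TestUncertaintyTest:
    def test_manual_jackknife_oracle(self, rng):
        X = rng.normal(size=(5, 3))
        y = rng.normal(size=5)
        res = uncertainty_test(X, y, n_factors=2)
        # written-out jack-knife sums
        b_full = fit_plsr(X, y, 2).coef_
        v = np.zeros(3)
        for i in range(5):
            keep = np.arange(5) != i
            b_i = fit_plsr(X[keep], y[keep], 2).coef_
            v += (b_full - b_i) ** 2
        v *= (5 - 1) / 5
        assert np.allclose(res.jackknife_variance, v)
        assert np.allclose(res.coef, b_full)

    def test_single_active_column_significant(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 4))
        y = 3.0 * X[:, 2]  # noise-free single active predictor
        res = uncertainty_test(X, y, n_factors=3)
        assert res.significant[2]

    def test_pure_noise_column_rarely_significant(self):
        # the noise column should clear alpha=0.05 in >= 90% of repetitions
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(10, 4))
            y = X[:, 0] + 0.3 * rng.normal(size=10)
            res = uncertainty_test(X, y, n_factors=2)
            hits += not res.significant[3]
        assert hits / n_rep >= 0.90

    def test_zero_variance_conventions(self, rng):
        # v==0, b==0 -> not significant; v==0, b!=0 -> significant.
        # duplicated-sample jack-knife: leaving out either copy gives the
        # same fit, so v==0 for every coefficient
        X = np.array([[1.0, 0.0], [1.0, 0.0], [-1.0, 0.0], [-1.0, 0.0]])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        res = uncertainty_test(X, y, n_factors=1)
        assert np.allclose(res.jackknife_variance, 0.0)
        assert res.significant[0]        # b != 0
        assert not res.significant[1]    # b == 0


class TestSignificantRegions:
    def test_empty_mask(self, grid):
        assert significant_regions(np.zeros(grid.size, bool), grid) == []

    def test_contiguous_run(self, grid):
        mask = (grid >= 5188) & (grid <= 5276)
        assert significant_regions(mask, grid) == [(5188.0, 5276.0)]

    def test_alternating_mask_enumeration(self, grid):
        mask = np.zeros(grid.size, bool)
        mask[::2] = True
        regions = significant_regions(mask, grid)
        assert len(regions) == int(mask.sum())
        assert all(lo == hi for lo, hi in regions)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, rng):
        from anthonir.preprocess import RECIPE_PHDIFF

        X = rng.normal(size=(9, 6))
        y = rng.normal(size=9)
        m = fit_plsr(X, y, 2, wavenumbers=np.arange(6.0))
        path = tmp_path / "model.json"
        save_model(m, path, recipe=RECIPE_PHDIFF)
        back, recipe_cfg = load_model(path)
        assert np.allclose(back.coef_, m.coef_)
        assert np.allclose(back.predict(X), m.predict(X))
        assert recipe_cfg["name"] == "phdiff"
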