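import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression as SklearnPLS

import hydrosar as h
from hydrosar.pls import PLSRegressionNIPALS, coefficients, fit_pls1, scores_tu


def _scale(M):
    return (M - M.mean(0)) / M.std(0, ddof=1)


class TestSingleComponent:
    def test_weight_is_normalised_covariance_direction(self, small_xy):
        X, y = small_xy
        m = PLSRegressionNIPALS(n_components=1).fit(X, y)
        Xs, ys = _scale(X.to_numpy()), _scale(y.to_numpy())
        w_direct = Xs.T @ ys
        w_direct /= np.linalg.norm(w_direct)
        if w_direct[np.argmax(np.abs(w_direct))] < 0:
            w_direct = -w_direct
        np.testing.assert_allclose(m.x_weights_[:, 0], w_direct, atol=1e-12)

    def test_orthogonal_response_explains_nothing(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 3)))
        # build y orthogonal to every centered/scaled column
        Xs = _scale(X.to_numpy())
        q, _ = np.linalg.qr(np.hstack([Xs, rng.normal(size=(12, 1))]))
        y = q[:, 3] - q[:, 3].mean()
        m = PLSRegressionNIPALS(n_components=1).fit(X, y)
        assert m.r2_[0] <= 1e-8


class TestFullRankEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_least_squares(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 10, 4
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        m = PLSRegressionNIPALS(n_components=p).fit(X, y)
        Xs, ys = _scale(X), _scale(y)
        b_ols, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        np.testing.assert_allclose(m.coef_, b_ols, atol=1e-8)
        np.testing.assert_allclose(
            m.predict(X), (Xs @ b_ols) * y.std(ddof=1) + y.mean(), atol=1e-8
        )


class TestModelInvariants:
    @pytest.mark.parametrize("a", [1, 2, 3])
    def test_orthogonal_scores_unit_weights_monotone_r2(self, small_xy, a):
        X, y = small_xy
        m = PLSRegressionNIPALS(n_components=a).fit(X, y)
        T = m.x_scores_
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() <= 1e-8 * np.diag(gram).max()
        np.testing.assert_allclose(
            np.linalg.norm(m.x_weights_, axis=0), 1.0, atol=1e-12
        )
        assert np.all(np.diff(m.r2_) >= -1e-12)
        assert 0.0 <= m.r2_[-1] <= 1.0 + 1e-12

    def test_column_reordering_leaves_predictions_unchanged(self, small_xy):
        X, y = small_xy
        m1 = PLSRegressionNIPALS(n_components=2).fit(X, y)
        perm = ["c", "a", "d", "b"]
        m2 = PLSRegressionNIPALS(n_components=2).fit(X[perm], y)
        np.testing.assert_allclose(
            m1.predict(X).to_numpy(), m2.predict(X[perm]).to_numpy(), atol=1e-8
        )

    def test_rank_excess_and_degenerate_y_rejected(self, rng):
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        with pytest.raises(ValueError, match="rank"):
            PLSRegressionNIPALS(n_components=4).fit(X, y)
        with pytest.raises(ValueError, match="variance"):
            PLSRegressionNIPALS(n_components=1).fit(X, np.ones(8))


class TestPredict:
    def test_training_predictions_equal_fitted_values(self, small_xy):
        X, y = small_xy
        m = PLSRegressionNIPALS(n_components=3).fit(X, y)
        fitted = (m.x_scores_ @ m.y_loadings_) * m.y_std_ + m.y_mean_
        np.testing.assert_allclose(m.predict(X).to_numpy(), fitted, atol=1e-10)

    def test_column_mean_row_predicts_response_mean(self, small_xy):
        X, y = small_xy
        m = PLSRegressionNIPALS(n_components=2).fit(X, y)
        at_mean = m.predict(X.mean().to_frame().T)
        assert at_mean.iloc[0] == pytest.approx(y.mean(), abs=1e-10)

    def test_noiseless_heldout_recovery(self, rng):
        X = rng.normal(size=(30, 5))
        beta = np.array([2.0, -1.0, 0.5, 3.0, -0.25])
        y = X @ beta
        m = PLSRegressionNIPALS(n_components=5).fit(X[:20], y[:20])
        np.testing.assert_allclose(m.predict(X[20:]), y[20:], atol=1e-6)

    def test_column_mismatch_listed(self, small_xy):
        X, y = small_xy
        m = PLSRegressionNIPALS(n_components=1).fit(X, y)
        bad = X.rename(columns={"a": "zz"})
        with pytest.raises(ValueError, match="zz"):
            m.predict(bad)


class TestCoefficients:
    def test_prediction_via_coefficients_matches_scores(self, small_xy):
        X, y = small_xy
        m = PLSRegressionNIPALS(n_components=2).fit(X, y)
        Xs = (X.to_numpy() - m.x_mean_) / m.x_std_
        via_coef = (Xs @ m.coef_) * m.y_std_ + m.y_mean_
        np.testing.assert_allclose(m.predict(X).to_numpy(), via_coef, atol=1e-10)

    def test_negating_response_negates_coefficients(self, small_xy):
        X, y = small_xy
        b_pos = coefficients(PLSRegressionNIPALS(n_components=2).fit(X, y))
        b_neg = coefficients(PLSRegressionNIPALS(n_components=2).fit(X, -y))
        np.testing.assert_allclose(b_pos.to_numpy(), -b_neg.to_numpy(), atol=1e-10)

    def test_planted_group_effect_signs(self, zscales):
        comp = h.generate_compositions(16, seed=3)
        truth = h.SyntheticTruth({"SCAA": 2.0, "PCAA": -1.0}, seed=3, noise_sd=0.0)
        y = h.generate_activity(comp, zscales, truth)
        x = h.group_sums(comp)
        b = coefficients(PLSRegressionNIPALS(n_components=2).fit(x, y))
        assert b["SCAA"] > 0 and b["PCAA"] < 0


class TestAgainstSklearn:
    """Cross-check: an independent NIPALS implementation must agree."""

    @pytest.mark.parametrize("a", [1, 2, 3])
    def test_predictions_match(self, a, rng):
        X = rng.normal(size=(14, 6))
        y = X @ rng.normal(size=6) + 0.3 * rng.normal(size=14)
        ours = PLSRegressionNIPALS(n_components=a).fit(X, y)
        ref = SklearnPLS(n_components=a, scale=True).fit(X, y.reshape(-1, 1))
        np.testing.assert_allclose(
            ours.predict(X), ref.predict(X).ravel(), atol=1e-8
        )


class TestScores:
    def test_noiseless_single_factor_inner_relation(self, rng):
        t = rng.normal(size=20)
        p = rng.normal(size=4)
        X = np.outer(t, p)
        X += 1e-9 * rng.normal(size=X.shape)  # break exact rank-1 degeneracy
        y = 2.0 * t
        m = PLSRegressionNIPALS(n_components=1).fit(X, y)
        (t1, u1), = scores_tu(m)
        assert abs(np.corrcoef(t1, u1)[0, 1]) >= 1 - 1e-8

    def test_first_component_has_strongest_inner_relation(self, small_xy):
        X, y = small_xy
        m = PLSRegressionNIPALS(n_components=3).fit(X, y)
        corrs = [abs(np.corrcoef(t, u)[0, 1]) for t, u in scores_tu(m)]
        assert corrs[0] >= max(corrs[1:]) - 1e-9

    def test_sample_permutation_equivariance(self, small_xy):
        X, y = small_xy
        perm = np.array([3, 1, 4, 0, 2, 9, 8, 7, 6, 5])
        m1 = PLSRegressionNIPALS(n_components=2).fit(X.to_numpy(), y.to_numpy())
        m2 = PLSRegressionNIPALS(n_components=2).fit(
            X.to_numpy()[perm], y.to_numpy()[perm]
        )
        np.testing.assert_allclose(m1.x_scores_[perm], m2.x_scores_, atol=1e-10)


def test_fit_pls1_on_prescaled_blocks(small_xy):
    X, y = small_xy
    xs, ys, _ = h.autoscale(X, y)
    m = fit_pls1(xs, ys, a=2)
    ref = PLSRegressionNIPALS(n_components=2, scale=True).fit(X, y)
    np.testing.assert_allclose(m.coef_, ref.coef_, atol=1e-10)
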