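"""PLS1 fitting, cross-validation, factor selection, VIP and band detection."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

import charterm as ct
from charterm.exceptions import RankDeficiencyError, ValidationError
from charterm.pls import _nipals, predict_centered


def _centered(rng, n, p):
    X = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    return X - X.mean(axis=0), y - y.mean()


class TestNIPALS:
    def test_rank_one_noiseless(self, rng):
        t = rng.normal(size=8)
        pvec = rng.normal(size=5)
        X = np.outer(t - t.mean(), pvec)
        y = 2 * (t - t.mean())
        m = ct.fit_pls1(X, y, 1)
        assert np.max(np.abs(predict_centered(m, X) - y)) < 1e-8

    def test_full_rank_equals_least_squares(self, rng):
        for _ in range(10):
            Xc, yc = _centered(rng, 6, 3)
            m = ct.fit_pls1(Xc, yc, 3)
            beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
            assert np.allclose(predict_centered(m, Xc), Xc @ beta, atol=1e-8)

    def test_orthonormal_columns_closed_form_weight(self, rng):
        # X with orthonormal columns: first weight is exactly Xᵀy normalised
        A = rng.normal(size=(12, 4))
        Q, _ = np.linalg.qr(A)
        y = rng.normal(size=12)
        yc = y - y.mean()
        m = ct.fit_pls1(Q, yc, 1)
        w_expected = Q.T @ yc
        w_expected /= np.linalg.norm(w_expected)
        assert np.allclose(np.abs(m.weights[:, 0]), np.abs(w_expected), atol=1e-10)

    def test_scores_orthogonal_and_weights_unit_norm(self, rng):
        for _ in range(25):
            Xc, yc = _centered(rng, 8, 6)
            m = ct.fit_pls1(Xc, yc, 5)
            T = m.scores
            gram = T.T @ T
            off = gram - np.diag(np.diag(gram))
            assert np.max(np.abs(off)) < 1e-8
            assert np.allclose(np.linalg.norm(m.weights, axis=0), 1, atol=1e-9)

    def test_deflation_exhausts_rank(self, rng):
        Xc, yc = _centered(rng, 6, 4)
        Xd = Xc.copy()
        W, P, q, T = _nipals(Xc, yc, 4, strict=False)
        for f in range(W.shape[1]):
            Xd -= np.outer(T[:, f], P[:, f])
        # after rank(X)=min(n-1,p) factors the residual block vanishes
        assert W.shape[1] == 4
        assert np.linalg.norm(Xd) < 1e-8

    def test_matches_reference_pls_at_every_factor_count(self, rng):
        for _ in range(20):
            n, p = 8, 5
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            Xc, yc = X - X.mean(0), y - y.mean()
            for F in range(1, 6):
                mine = predict_centered(ct.fit_pls1(Xc, yc, F), Xc) + y.mean()
                ref = PLSRegression(n_components=F, scale=False).fit(X, y)
                assert np.allclose(mine, ref.predict(X).ravel(), atol=1e-6)

    def test_error_paths(self, rng):
        Xc, yc = _centered(rng, 6, 4)
        with pytest.raises(ValidationError, match="zero variance"):
            ct.fit_pls1(Xc, np.zeros(6), 1)
        with pytest.raises(RankDeficiencyError):
            ct.fit_pls1(Xc, yc, 6)

    def test_regression_vector_agrees_with_sequential_prediction(self, rng):
        """Deflation-path prediction equals the accumulated regression vector."""
        Xc, yc = _centered(rng, 10, 7)
        m = ct.fit_pls1(Xc, yc, 3)
        Xnew = rng.normal(size=(4, 7))
        assert np.allclose(predict_centered(m, Xnew), Xnew @ m.regression_vector, atol=1e-9)


class TestAIC:
    def test_arithmetic(self):
        assert ct.aic(10.0, 6, 1) == pytest.approx(6 * np.log(100) + 4)

    def test_monotone_in_rmsecv_and_penalty_structure(self):
        assert ct.aic(5.0, 6, 2) < ct.aic(6.0, 6, 2)
        assert ct.aic(5.0, 6, 3) - ct.aic(5.0, 6, 2) == pytest.approx(2.0)

    def test_zero_rmsecv_sentinel(self):
        assert ct.aic(0.0, 6, 1) == -np.inf

    @pytest.mark.parametrize(
        "aics,expected",
        [([10, 8, 8, 9], 2), ([10, 9, 8, 7], 4), ([5], 1)],
    )
    def test_select_n_factors(self, aics, expected):
        assert ct.select_n_factors(aics) == expected


class TestLOOCV:
    def test_uninformative_x_closed_form(self):
        """With no usable predictor signal every held-out prediction is the
        training-fold mean, giving RMSECV = sqrt(10500) on the 350-600 grid."""
        X = np.tile(np.linspace(0.0, 1.0, 250), (6, 1))  # identical rows
        y = np.array([350.0, 400, 450, 500, 550, 600])
        cv = ct.loo_cv(X, y, f_max=4, use_snv=False)
        assert np.allclose(cv.per_factor_rmsecv, np.sqrt(10500), atol=1e-9)
        errors = (6 * y - 2850) / 5
        assert np.allclose(cv.predicted - y, -errors, atol=1e-9)

    def test_perfect_rank_one_relation(self, rng):
        """Noiseless spectra are affine in T, so with the linear pipeline
        (no SNV, unit filter window) a 1-factor model cross-validates exactly.
        SNV is a ratio transform and breaks exact affinity, so it is off here."""
        cfg = ct.taxon_preset("Olea")
        from dataclasses import replace

        cal = ct.simulate_calibration(replace(cfg, noise_sd=0.0, scatter_sd=0.0), seed=0)
        cv = ct.loo_cv(cal.matrix, cal.temperatures, f_max=2, window=1, use_snv=False)
        assert cv.per_factor_rmsecv[0] < 1e-6
        assert cv.r2 > 1 - 1e-9

    def test_sample_order_invariance(self, rng):
        X = rng.normal(size=(7, 30))
        y = rng.normal(size=7) * 50 + 450
        cv1 = ct.loo_cv(X, y, f_max=3)
        perm = rng.permutation(7)
        cv2 = ct.loo_cv(X[perm], y[perm], f_max=3)
        assert np.allclose(np.sort(cv1.per_factor_rmsecv), np.sort(cv2.per_factor_rmsecv), atol=1e-9)
        assert np.allclose(cv1.per_factor_rmsecv, cv2.per_factor_rmsecv, atol=1e-9)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValidationError):
            ct.loo_cv(rng.normal(size=(2, 10)), np.array([1.0, 2.0]), f_max=1)


class TestVIP:
    def test_normalisation_identity_on_random_models(self, rng):
        for _ in range(20):
            Xc, yc = _centered(rng, 8, 12)
            m = ct.fit_pls1(Xc, yc, 3)
            v = ct.vip(m).values
            assert np.all(v >= 0)
            assert np.sum(v**2) == pytest.approx(12, rel=1e-6)

    def test_single_factor_reduces_to_scaled_weight(self, rng):
        Xc, yc = _centered(rng, 8, 10)
        m = ct.fit_pls1(Xc, yc, 1)
        v = ct.vip(m).values
        w = m.weights[:, 0]
        assert np.allclose(v, np.sqrt(10) * np.abs(w) / np.linalg.norm(w), atol=1e-10)

    def test_uniform_weights_give_unit_vip(self):
        p = 16
        w = np.full((p, 1), 1 / np.sqrt(p))
        m = ct.PLSModel(1, w, w.copy(), np.array([2.0]), np.ones((4, 1)))
        assert np.allclose(ct.vip(m).values, 1.0)


class TestDiagnosticBands:
    def test_flat_profile_has_no_bands(self):
        assert ct.diagnostic_bands(np.ones(50), np.linspace(1800, 400, 50)) == []

    def test_single_informative_band_recovered(self):
        """A generator whose only temperature-sensitive band is 1730 cm^-1
        yields a diagnostic band within one grid step of 1730."""
        cfg = ct.GeneratorConfig(
            bands=[
                ct.BandSpec(1730.0, 12.0, 0.5, -4e-4),
                ct.BandSpec(1040.0, 12.0, 0.8, 0.0),
            ]
        )
        cal = ct.simulate_calibration(cfg, seed=1)
        est = ct.TemperaturePLS().fit(cal.matrix, cal.temperatures)
        bands = est.diagnostic_bands()
        step = (1800 - 400) / 249
        assert any(abs(b - 1730) <= step for b in bands)

    def test_min_separation_keeps_one_of_two_close_bands(self):
        grid = np.linspace(1800, 400, 250)
        v = np.ones(250) * 0.2
        for c, h in ((1400.0, 3.0), (1370.0, 2.0)):
            v += h * np.exp(-((grid - c) ** 2) / (2 * 4.0**2))
        assert len(ct.diagnostic_bands(v, grid, min_separation=50)) == 1
        assert len(ct.diagnostic_bands(v, grid, min_separation=20)) == 2


class TestTemperaturePLS:
    def test_train_set_replay_and_aic_choice(self, olea_model):
        cfg, cal, est = olea_model
        # predicting the calibration matrix reproduces the training fit
        yhat = est.predict(cal.matrix)
        m = est.model_
        from charterm.preprocess import apply_preprocess

        Xp = apply_preprocess(cal.matrix.values, m.preprocess_state)
        train = predict_centered(m, Xp) + m.preprocess_state.y_mean
        assert np.allclose(yhat, train, atol=1e-10)
        assert est.n_factors_ == est.cv_.chosen_factors

    def test_noiseless_heldout_prediction_exact(self):
        from dataclasses import replace

        cfg = replace(ct.taxon_preset("Olea"), noise_sd=0.0, scatter_sd=0.0)
        cal = ct.simulate_calibration(cfg, seed=0)
        est = ct.TemperaturePLS(n_factors=1, window=1, snv=False).fit(
            cal.matrix, cal.temperatures
        )
        held = ct.simulate_archaeological(cfg, 475.0, 1, seed=9)
        assert est.predict(held)[0] == pytest.approx(475.0, abs=1e-6)
        # the full stack (SNV on) is only approximately linear in T
        full = ct.TemperaturePLS(n_factors="aic").fit(cal.matrix, cal.temperatures)
        assert full.predict(held)[0] == pytest.approx(475.0, abs=10.0)

    def test_predictions_not_clipped(self, olea_model):
        """Extrapolation beyond the 350-600 degC range is reported as-is."""
        cfg, cal, est = olea_model
        hot = ct.simulate_archaeological(cfg, 650.0, 3, seed=4)
        assert est.predict(hot).mean() > 600.0

    def test_grid_mismatch_rejected(self, olea_model):
        _, _, est = olea_model
        with pytest.raises(ValidationError):
            est.predict(np.zeros((1, 249)))

    def test_sklearn_params_roundtrip(self):
        est = ct.TemperaturePLS(window=7)
        assert est.get_params()["window"] == 7
        est.set_params(f_max=3)
        assert est.f_max == 3

    def test_serialization_roundtrip(self, olea_model, tmp_path):
        cfg, cal, est = olea_model
        path = tmp_path / "model.json"
        est.model_.save(path)
        loaded = ct.PLSModel.load(path)
        arch = ct.simulate_archaeological(cfg, 500.0, 3, seed=2)
        assert np.allclose(ct.predict(loaded, arch), est.predict(arch), atol=1e-12)
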