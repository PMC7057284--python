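"""Single-trial GLM: HRF shape, LSA design, high-pass filter, OLS, t-conversion."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fairdecode.glm import (BoldRun, DesignMatrix, betas_to_t, build_lsa_design,
                            double_gamma_hrf, fit_glm, gaussian_highpass,
                            nuisance_regressors, validate_events)
from fairdecode.volumes import FWHM_TO_SIGMA


def oracle_regressor(start: float, stop: float, times: np.ndarray,
                     dt: float = 0.1) -> np.ndarray:
    """Independent convolution of a boxcar with the double-gamma kernel."""
    n_fine = int(np.ceil(times.max() / dt)) + 1
    fine = np.arange(n_fine) * dt
    box = ((fine >= start) & (fine < stop)).astype(float)
    hrf = double_gamma_hrf(dt)
    conv = np.convolve(box, hrf)[:n_fine] * dt
    idx = np.rint(times / dt).astype(int)
    return conv[idx]


class TestDoubleGammaHrf:
    def test_zero_at_onset(self):
        h = double_gamma_hrf(0.1)
        assert h[0] == 0.0

    def test_unit_peak_in_5_to_7_s(self):
        dt = 0.1
        h = double_gamma_hrf(dt)
        assert h.max() == pytest.approx(1.0)
        assert 5.0 <= np.argmax(h) * dt <= 7.0

    def test_single_sign_change_after_peak(self):
        h = double_gamma_hrf(0.05)
        post = h[np.argmax(h):]
        signs = np.sign(post[np.abs(post) > 1e-12])
        changes = np.sum(np.diff(signs) != 0)
        assert changes == 1  # positive lobe then a single undershoot

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            double_gamma_hrf(0.0)
        with pytest.raises(ValueError):
            double_gamma_hrf(0.1, length_s=10.0)

    def test_matches_canonical_reference_implementation(self):
        nilearn_hrf = pytest.importorskip(
            "nilearn.glm.first_level.hemodynamic_models")
        dt = 0.1
        mine = double_gamma_hrf(dt, length_s=32.0)
        ref = nilearn_hrf.spm_hrf(1.0, oversampling=int(1 / dt),
                                  time_length=32.0)
        ref = ref / ref.max()
        n = min(len(mine), len(ref))
        # same canonical parameterization; small sampling-offset differences
        assert np.max(np.abs(mine[:n] - ref[:n])) < 0.05
        assert abs(int(np.argmax(mine)) - int(np.argmax(ref))) <= 2


class TestLsaDesign:
    def test_standard_session_has_48_trial_columns(self, pattern_study):
        events = pattern_study.subjects[0].events
        n_vol = int(np.ceil((events["onset"].iloc[-1] + 40) / 2.0))
        design = build_lsa_design(events, n_vol, 2.0)
        assert design.n_trials == 48
        assert design.column_names[-1] == "intercept"

    def test_zero_trials_gives_nuisance_plus_intercept(self):
        events = pd.DataFrame(columns=["onset", "duration", "game", "opponent",
                                       "response_time", "offer"])
        design = build_lsa_design(events, 20, 2.0,
                                  nuisance={"background": np.sin(np.arange(20.0))})
        assert design.matrix.shape == (20, 2)
        assert design.n_trials == 0

    def test_single_trial_matches_convolution_oracle(self, simple_events):
        events = simple_events.iloc[:1]
        tr, n_vol = 2.0, 20
        design = build_lsa_design(events, n_vol, tr)
        times = np.arange(n_vol) * tr
        # keypress at 12 s -> boxcar over [6, 12] s
        expect = oracle_regressor(6.0, 12.0, times)
        assert np.allclose(design.matrix[:, 0], expect, atol=1e-12)

    def test_epoch_before_run_start_names_trial(self, simple_events):
        bad = simple_events.copy()
        bad.loc[0, "onset"] = -4.0
        bad.loc[0, "response_time"] = -2.0
        with pytest.raises(ValueError, match="trial 0"):
            build_lsa_design(bad, 50, 2.0)

    def test_keypress_after_run_end_rejected(self, simple_events):
        with pytest.raises(ValueError, match="after the run end"):
            build_lsa_design(simple_events, 10, 2.0)

    def test_event_validation(self, simple_events):
        bad = simple_events.copy()
        bad.loc[1, "offer"] = 3.0  # off the 2-euro grid
        with pytest.raises(ValueError, match="grid"):
            validate_events(bad)
        bad = simple_events.copy()
        bad.loc[1, "onset"] = 0.0  # non-increasing
        with pytest.raises(ValueError, match="strictly increasing"):
            validate_events(bad)


class TestGaussianHighpass:
    def test_constant_series_unchanged(self):
        y = np.full(120, 7.0)
        assert np.allclose(gaussian_highpass(y, 100.0, 2.0), y)

    @pytest.mark.parametrize("period_s, tol", [(256.0, 0.03), (300.0, 0.03)])
    def test_slow_cosine_attenuation_matches_analytic_transfer(self, period_s, tol):
        # interior response of the Gaussian running-line smoother is the
        # Gaussian-weighted mean, so the high-pass residual of a cosine of
        # frequency f has amplitude 1 - exp(-2 pi^2 sigma^2 f^2)
        tr, n = 2.0, 540
        t = np.arange(n) * tr
        y = np.cos(2 * np.pi * t / period_s)
        out = gaussian_highpass(y, 100.0, tr)
        sigma_s = 100.0 * FWHM_TO_SIGMA
        predicted = 1.0 - np.exp(-2 * np.pi**2 * (sigma_s / period_s) ** 2)
        sl = slice(60, n - 60)  # interior, away from boundary line fits
        c, s = np.cos(2 * np.pi * t / period_s)[sl], np.sin(2 * np.pi * t / period_s)[sl]
        resid = out[sl] - out[sl].mean()
        amp = np.hypot(2 * np.mean(resid * c), 2 * np.mean(resid * s))
        assert amp == pytest.approx(predicted, abs=tol)

    def test_fast_cosine_preserved(self):
        tr, n = 2.0, 300
        t = np.arange(n) * tr
        y = np.cos(2 * np.pi * t / 10.0) + 5.0
        out = gaussian_highpass(y, 100.0, tr)
        sl = slice(30, n - 30)
        c, s = np.cos(2 * np.pi * t / 10.0)[sl], np.sin(2 * np.pi * t / 10.0)[sl]
        resid = out[sl] - out[sl].mean()
        amp = np.hypot(2 * np.mean(resid * c), 2 * np.mean(resid * s))
        assert amp >= 0.95
        assert out.mean() == pytest.approx(y.mean(), abs=1e-6)

    def test_white_noise_variance_roughly_preserved(self):
        rng = np.random.default_rng(11)
        y = rng.normal(0, 1, size=(400, 100))
        out = gaussian_highpass(y, 100.0, 2.0)
        ratio = out.var(axis=0).mean() / y.var(axis=0).mean()
        assert 0.75 <= ratio <= 1.25

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            gaussian_highpass(np.zeros(2), 100.0, 2.0)
        with pytest.raises(ValueError, match="FWHM"):
            gaussian_highpass(np.zeros(50), 3.0, 2.0)


def _toy_run(n_vol=30, n_vox=5, seed=0):
    rng = np.random.default_rng(seed)
    x = np.column_stack([rng.normal(size=(n_vol, 3)), np.ones(n_vol)])
    design = DesignMatrix(x, ["trial_000", "trial_001", "trial_002", "intercept"],
                          [0, 1, 2])
    beta_true = rng.normal(size=(4, n_vox))
    mask = np.ones((n_vox, 1, 1), bool)
    return x, design, beta_true, mask


class TestFitGlm:
    def test_noise_free_recovery(self):
        x, design, beta_true, mask = _toy_run()
        y = x @ beta_true
        bold = BoldRun(y.T.reshape(5, 1, 1, -1), 2.0, mask)
        fit = fit_glm(bold, design)
        assert np.allclose(fit.betas, beta_true, atol=1e-8)
        assert np.allclose(fit.residual_variance, 0.0, atol=1e-12)

    def test_matches_normal_equations_oracle(self):
        x, design, beta_true, mask = _toy_run(seed=5)
        rng = np.random.default_rng(6)
        y = x @ beta_true + rng.normal(0, 0.5, size=(30, 5))
        bold = BoldRun(y.T.reshape(5, 1, 1, -1), 2.0, mask)
        fit = fit_glm(bold, design)
        oracle = np.linalg.inv(x.T @ x) @ x.T @ y
        assert np.allclose(fit.betas, oracle, atol=1e-8)
        resid = y - x @ oracle
        assert np.allclose(fit.residual_variance,
                           (resid**2).sum(axis=0) / (30 - 4), atol=1e-10)

    def test_pure_noise_betas_average_zero(self):
        x, design, _, mask = _toy_run(n_vox=1)
        rng = np.random.default_rng(2)
        betas = []
        for _ in range(500):
            y = rng.normal(size=(30, 1))
            bold = BoldRun(y.T.reshape(1, 1, 1, -1), 2.0, mask[:1])
            betas.append(fit_glm(bold, design).betas[0, 0])
        se = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert abs(np.mean(betas)) < 3 * se

    def test_rank_deficient_design_names_columns(self):
        x, design, _, mask = _toy_run()
        bad = x.copy()
        bad[:, 1] = 2 * bad[:, 0]
        design_bad = DesignMatrix(bad, design.column_names, design.trial_columns)
        rng = np.random.default_rng(0)
        bold = BoldRun(rng.normal(size=(5, 1, 1, 30)), 2.0, mask)
        with pytest.raises(ValueError, match="rank deficient"):
            fit_glm(bold, design_bad)


class TestBetasToT:
    def _events(self, n):
        return pd.DataFrame({
            "onset": 22.0 * np.arange(n), "duration": 6.0,
            "game": ["UG", "DG"] * (n // 2) + ["UG"] * (n % 2),
            "opponent": "human",
            "response_time": 22.0 * np.arange(n) + 12.0, "offer": 8.0})

    def test_orthonormal_design_gives_t_equal_beta(self):
        rng = np.random.default_rng(1)
        q, _ = np.linalg.qr(rng.normal(size=(8, 3)))  # orthonormal columns
        design = DesignMatrix(q, ["trial_000", "trial_001", "intercept"], [0, 1])
        y = rng.normal(size=(8, 3))
        bold = BoldRun(y.T.reshape(3, 1, 1, 8), 2.0, np.ones((3, 1, 1), bool))
        fit = fit_glm(bold, design)
        fit.residual_variance[:] = 1.0  # with unit sigma^2, t reduces to beta
        tp = betas_to_t(fit, self._events(2))
        assert np.allclose(tp.values, fit.betas[[0, 1]], atol=1e-12)

    def test_two_trial_design_matches_hand_computed_se(self):
        # X = [[1, 0], [1, 1], [0, 1], [0, 0]] plus intercept
        x = np.array([[1.0, 0, 1], [1, 1, 1], [0, 1, 1], [0, 0, 1]])
        design = DesignMatrix(x, ["trial_000", "trial_001", "intercept"], [0, 1])
        y = np.array([[2.0], [3.0], [1.5], [1.0]])
        bold = BoldRun(y.T.reshape(1, 1, 1, 4), 2.0, np.ones((1, 1, 1), bool))
        fit = fit_glm(bold, design)
        xtx_inv = np.linalg.inv(x.T @ x)
        beta = xtx_inv @ x.T @ y[:, 0]
        sigma2 = np.sum((y[:, 0] - x @ beta) ** 2) / (4 - 3)
        expect_t = beta[:2] / np.sqrt(sigma2 * np.diag(xtx_inv)[:2])
        tp = betas_to_t(fit, self._events(2))
        assert np.allclose(tp.values[:, 0], expect_t, atol=1e-10)

    def test_doubling_noise_halves_expected_abs_t(self):
        rng = np.random.default_rng(8)
        n_vol = 40
        x = np.column_stack([rng.normal(size=(n_vol, 2)), np.ones(n_vol)])
        design = DesignMatrix(x, ["trial_000", "trial_001", "intercept"], [0, 1])
        beta = np.array([1.0, 0.5, 0.0])
        t_means = []
        for noise_sd in (1.0, 2.0):
            ts = []
            for _ in range(300):
                y = x @ beta + rng.normal(0, noise_sd, n_vol)
                bold = BoldRun(y.reshape(1, 1, 1, -1), 2.0,
                               np.ones((1, 1, 1), bool))
                tp = betas_to_t(fit_glm(bold, design), self._events(2))
                ts.append(np.abs(tp.values[:, 0]))
            t_means.append(np.mean(ts))
        assert t_means[0] / t_means[1] == pytest.approx(2.0, rel=0.15)

    def test_zero_residual_variance_capped_with_warning(self):
        x = np.array([[1.0, 1], [0, 1], [1, 1], [0, 1]])
        design = DesignMatrix(x, ["trial_000", "intercept"], [0])
        y = x @ np.array([2.0, 1.0])
        bold = BoldRun(y.reshape(1, 1, 1, -1), 2.0, np.ones((1, 1, 1), bool))
        fit = fit_glm(bold, design)
        with pytest.warns(RuntimeWarning, match="zero residual variance"):
            tp = betas_to_t(fit, self._events(1), t_cap=99.0)
        assert tp.values[0, 0] == 99.0


class TestEndToEndPatterns:
    def test_trial_pattern_rows_equal_event_rows(self, bold_study):
        from fairdecode.glm import estimate_trial_patterns

        sub = bold_study.subjects[0]
        tp = estimate_trial_patterns(sub.bold, sub.events,
                                     wm_mask=bold_study.masks["wm_like"])
        assert tp.n_trials == len(sub.events) == 48
        assert np.all(np.isfinite(tp.values))

    def test_lsa_recovers_planted_amplitudes(self):
        # per-trial amplitude jitter; correlation(beta, truth) > 0.9
        from fairdecode.simulate import SimConfig, _study_masks, simulate_offers, build_events
        from fairdecode.glm import build_lsa_design, fit_glm

        config = SimConfig(seed=9, grid_shape=(8, 8, 8))
        masks = _study_masks(config)
        events = build_events(simulate_offers(0.5, 6, 1.5, 3, config), config, 3)
        rng = np.random.default_rng(4)
        amps = rng.uniform(0.5, 2.0, size=len(events))
        n_vol = int(np.ceil((events["onset"].iloc[-1] + 42) / 2.0))
        design = build_lsa_design(events, n_vol, 2.0)
        vox = design.matrix[:, design.trial_columns] @ amps
        y = vox + rng.normal(0, 0.05, n_vol)
        bold = BoldRun(y.reshape(1, 1, 1, -1), 2.0, np.ones((1, 1, 1), bool))
        fit = fit_glm(bold, design)
        got = fit.betas[design.trial_columns, 0]
        assert np.corrcoef(got, amps)[0, 1] > 0.9

    def test_nuisance_regressors_shapes(self, bold_study):
        sub = bold_study.subjects[0]
        nuis = nuisance_regressors(sub.bold, bold_study.masks["wm_like"])
        assert set(nuis) == {"background", "white_matter"}
        for series in nuis.values():
            assert series.shape == (sub.bold.n_volumes,)
            assert abs(series.mean()) < 1e-10
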