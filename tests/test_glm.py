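import numpy as np
import pytest
from scipy import stats

from cravemap import glm, synth
from cravemap.glm import GlmError
from tests.conftest import toy_events


class TestCanonicalHrf:
    def test_zero_at_origin(self):
        assert glm.canonical_hrf(np.array([0.0]))[0] == 0.0

    def test_peak_near_five_seconds(self):
        t = np.arange(0, 32, 0.1)
        h = glm.canonical_hrf(t)
        assert t[np.argmax(h)] == pytest.approx(5.0, abs=0.15)
        assert h.max() == pytest.approx(1.0, abs=1e-6)

    def test_tail_small_at_32s(self):
        tail = glm.canonical_hrf(np.array([0.0, 32.0]))[1]
        assert abs(tail) < 0.01

    def test_undershoot_present(self):
        t = np.arange(0, 32, 0.1)
        h = glm.canonical_hrf(t)
        assert h[(t > 10) & (t < 20)].min() < 0

    def test_negative_times_rejected(self):
        with pytest.raises(GlmError):
            glm.canonical_hrf(np.array([-1.0, 0.0]))


class TestHighpassBasis:
    def test_study_column_count(self):
        # floor(2 * 380 * 2 / 128) = 11
        assert glm.highpass_basis(380, 2.0).shape == (380, 11)

    def test_cutoff_to_zero_gives_no_columns(self):
        assert glm.highpass_basis(380, 2.0, cutoff_hz=1e-6).shape[1] == 0

    def test_captures_sub_cutoff_cosine(self):
        n, tr = 380, 2.0
        t = np.arange(n) * tr
        target = np.cos(2 * np.pi * t / 256.0)
        basis = np.column_stack([np.ones(n), glm.highpass_basis(n, tr)])
        beta, *_ = np.linalg.lstsq(basis, target, rcond=None)
        resid = target - basis @ beta
        r2 = 1 - resid.var() / target.var()
        assert r2 > 0.99

    def test_invalid_inputs(self):
        with pytest.raises(GlmError):
            glm.highpass_basis(1, 2.0)
        with pytest.raises(GlmError):
            glm.highpass_basis(100, 2.0, cutoff_hz=0.0)


class TestDesignMatrix:
    def _motion(self, n):
        return synth.simulate_motion(n, np.random.default_rng(0))

    def test_univariate_columns(self, run_events, small_config):
        dm = glm.build_design_matrix(run_events, "univariate",
                                     self._motion(380), 2.0, 380)
        assert dm.condition_columns == ["positive", "negative", "now"]
        for name in ("rating", "iti", "constant"):
            assert name in dm.matrix.columns
        assert sum(c.startswith("motion_") for c in dm.matrix.columns) == 6
        assert sum(c.startswith("drift_") for c in dm.matrix.columns) == 11

    def test_mvpa_columns(self, run_events):
        dm = glm.build_design_matrix(run_events, "mvpa", self._motion(380), 2.0, 380)
        assert dm.condition_columns == ["positive_cue1", "positive_cue2",
                                        "negative_cue1", "negative_cue2"]
        assert "now" in dm.matrix.columns  # control epochs kept as nuisance

    def test_beta_series_one_column_per_regulation_trial(self, run_events):
        dm = glm.build_design_matrix(run_events, "beta_series",
                                     self._motion(380), 2.0, 380)
        n_reg = (run_events["condition"] != "now").sum()
        assert len(dm.condition_columns) == n_reg == 24
        assert set(dm.trial_conditions.values()) == {"positive", "negative"}

    def test_rows_equal_frames_and_names_unique(self, run_events):
        dm = glm.build_design_matrix(run_events, "univariate",
                                     self._motion(380), 2.0, 380)
        assert dm.n_frames == 380
        assert dm.matrix.columns.is_unique

    def test_event_beyond_run_end_rejected(self):
        ev = toy_events(3, spacing=30.0)
        ev.loc[2, "onset"] = 200.0
        with pytest.raises(GlmError, match="beyond"):
            glm.build_design_matrix(ev, "univariate", self._motion(100), 2.0, 100)

    def test_bad_motion_rejected(self, run_events):
        with pytest.raises(GlmError, match="motion"):
            glm.build_design_matrix(run_events, "univariate",
                                    np.zeros((380, 5)), 2.0, 380)

    def test_unknown_mode_rejected(self, run_events):
        with pytest.raises(GlmError, match="mode"):
            glm.build_design_matrix(run_events, "trialwise",
                                    self._motion(380), 2.0, 380)


def _fit_on_signal(rho, noise_sd, amp=1.5, seed=0, n_frames=380):
    """Single-run simulated voxel fit; returns (fit, design, true amp)."""
    rng = np.random.default_rng(seed)
    ev = toy_events(18, spacing=40.0, duration=8.0)
    motion = synth.simulate_motion(n_frames, rng)
    dm = glm.build_design_matrix(ev, "univariate", motion, 2.0, n_frames)
    x = dm.matrix["positive"].to_numpy()
    noise = synth.ar1_noise((1, n_frames), rho, noise_sd, rng)[0]
    y = 100.0 + amp * x + noise
    return glm.fit_glm(y[:, None], dm), dm, amp


class TestFitGlm:
    def test_noiseless_machine_precision(self):
        fit, dm, amp = _fit_on_signal(rho=0.0, noise_sd=0.0)
        j = dm.matrix.columns.get_loc("positive")
        assert fit.betas[j, 0] == pytest.approx(amp, abs=1e-9)
        assert fit.rho == 0.0

    def test_white_noise_rho_near_zero(self):
        rhos = [_fit_on_signal(rho=0.0, noise_sd=1.0, seed=s)[0].rho
                for s in range(8)]
        assert abs(np.mean(rhos)) < 0.05

    def test_ar1_rho_recovered(self):
        rhos = [_fit_on_signal(rho=0.4, noise_sd=1.0, seed=s)[0].rho
                for s in range(8)]
        assert 0.3 < np.mean(rhos) < 0.5
        assert all(0.25 < r < 0.55 for r in rhos)

    def test_whitening_removes_autocorrelation(self):
        rng = np.random.default_rng(3)
        ev = toy_events(18, spacing=40.0)
        motion = synth.simulate_motion(380, rng)
        dm = glm.build_design_matrix(ev, "univariate", motion, 2.0, 380)
        noise = synth.ar1_noise((200, 380), 0.4, 1.0, rng).T
        fit = glm.fit_glm(noise, dm)
        xw = glm._ar1_whiten(dm.values(), fit.rho)
        yw = glm._ar1_whiten(noise, fit.rho)
        resid = yw - xw @ fit.betas
        lag1 = np.sum(resid[1:] * resid[:-1]) / np.sum(resid ** 2)
        assert abs(lag1) < 0.05

    def test_rank_deficiency_rejected(self, run_events):
        motion = np.zeros((380, 6))  # demeaned constants are collinear
        dm = glm.build_design_matrix(run_events, "univariate", motion, 2.0, 380)
        with pytest.raises(GlmError, match="rank"):
            glm.fit_glm(np.random.default_rng(0).standard_normal((380, 2)), dm)

    def test_fewer_frames_than_columns_rejected(self):
        import pandas as pd
        ev = pd.DataFrame({"onset": [1.0, 4.0, 7.0], "duration": [2.0] * 3,
                           "condition": ["positive", "negative", "now"],
                           "cue_id": [1, 2, 1], "stimulus_id": [0, 1, 2],
                           "run": [1, 1, 1]})
        motion = synth.simulate_motion(6, np.random.default_rng(0))
        dm = glm.build_design_matrix(ev, "univariate", motion, 2.0, 6)
        with pytest.raises(GlmError, match="frames"):
            glm.fit_glm(np.zeros((6, 1)), dm)

    def test_nuisance_invariance_on_noiseless_data(self):
        fit_full, dm, amp = _fit_on_signal(rho=0.0, noise_sd=0.0)
        keep = [c for c in dm.matrix.columns if c not in ("rating", "iti")]
        reduced = glm.DesignMatrix(matrix=dm.matrix[keep],
                                   frame_times=dm.frame_times,
                                   condition_columns=dm.condition_columns,
                                   mode=dm.mode)
        fit_red = glm.fit_glm(
            (100.0 + amp * dm.matrix["positive"].to_numpy())[:, None], reduced)
        j_full = dm.matrix.columns.get_loc("positive")
        j_red = keep.index("positive")
        assert fit_full.betas[j_full, 0] == pytest.approx(
            fit_red.betas[j_red, 0], abs=1e-9)


class TestComputeContrast:
    def test_zero_weights_zero_map(self):
        fit, dm, _ = _fit_on_signal(rho=0.0, noise_sd=1.0)
        cmap = glm.compute_contrast(fit, {})
        assert np.all(cmap.effect == 0)
        assert np.all(cmap.t == 0)

    def test_regulation_contrast_positive_in_planted_region(self, small_config,
                                                            run_events, rng):
        region = np.zeros(small_config.grid_shape, dtype=bool)
        region[3:5, 3:5, 3:5] = True
        spec = synth.EffectSpec(
            noise_sd=0.0, ar1_rho=0.0,
            univariate_regions={"positive": (region, 1.0),
                                "negative": (region, 1.0)})
        vol = synth.simulate_bold(run_events, spec, small_config, rng)
        motion = synth.simulate_motion(small_config.n_volumes,
                                       np.random.default_rng(1))
        dm = glm.build_design_matrix(run_events, "univariate", motion,
                                     small_config.tr_s, small_config.n_volumes)
        fit = glm.fit_glm(vol, dm, synth.brain_mask(small_config.grid_shape))
        cmap = glm.compute_contrast(fit, {"positive": 0.5, "negative": 0.5,
                                          "now": -1.0})
        assert np.nanmean(cmap.effect[region]) == pytest.approx(1.0, abs=1e-6)

    def test_null_t_distribution_quantile(self):
        rng = np.random.default_rng(5)
        ev = toy_events(12, spacing=30.0)
        motion = synth.simulate_motion(200, rng)
        dm = glm.build_design_matrix(ev, "univariate", motion, 2.0, 200)
        y = rng.standard_normal((200, 4000))
        fit = glm.fit_glm(y, dm)
        cmap = glm.compute_contrast(fit, {"positive": 1.0, "now": -1.0})
        q95 = np.quantile(cmap.t, 0.95)
        expected = stats.t.ppf(0.95, fit.df)
        assert q95 == pytest.approx(expected, abs=0.1)

    def test_unknown_column_rejected(self):
        fit, _, _ = _fit_on_signal(rho=0.0, noise_sd=1.0)
        with pytest.raises(GlmError, match="unknown"):
            glm.compute_contrast(fit, {"nope": 1.0})


class TestSmoothing:
    def test_fwhm_zero_identity(self, rng):
        data = rng.standard_normal((8, 8, 8))
        np.testing.assert_array_equal(glm.smooth_volume(data, 0.0, 3.0), data)

    def test_impulse_half_maximum_radius(self):
        data = np.zeros((21, 21, 21))
        data[10, 10, 10] = 1.0
        sm = glm.smooth_volume(data, 8.0, 3.0)
        profile = sm[10:, 10, 10]
        half = sm[10, 10, 10] / 2
        # FWHM 8 mm -> half max at 4 mm, i.e. between voxels 1 and 2 (3/6 mm)
        crossing = np.interp(0.5, (profile / (2 * half))[::-1],
                             np.arange(len(profile))[::-1]) * 3.0
        assert crossing == pytest.approx(4.0, abs=0.5)

    def test_global_mean_preserved(self, rng):
        data = rng.standard_normal((12, 12, 12))
        sm = glm.smooth_volume(data, 8.0, 3.0)
        assert sm.mean() == pytest.approx(data.mean(), abs=1e-12)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(GlmError):
            glm.smooth_volume(np.zeros((4, 4, 4)), -1.0, 3.0)

    def test_nan_background_preserved(self, rng):
        data = rng.standard_normal((10, 10, 10))
        data[0] = np.nan
        sm = glm.smooth_volume(data, 6.0, 3.0)
        assert np.isnan(sm[0]).all()
        assert np.isfinite(sm[5]).all()


class TestParameterRecoveryBias:
    def test_bias_below_two_percent_with_noise(self):
        est = []
        for s in range(30):
            fit, dm, amp = _fit_on_signal(rho=0.3, noise_sd=1.0, seed=100 + s)
            j = dm.matrix.columns.get_loc("positive")
            est.append(fit.betas[j, 0])
        bias = abs(np.mean(est) - 1.5) / 1.5
        assert bias < 0.02
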