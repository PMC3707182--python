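"""HRF, design construction, filtering, beta estimation, FIR and SVD."""

import numpy as np
import pandas as pd
import pytest

import seqmvpa as sm
from seqmvpa import glm, synthgen


class TestCanonicalHRF:
    def test_positive_integral_and_truncation(self):
        h = glm.canonical_hrf(0.1)
        assert h.sum() == pytest.approx(1.0)
        assert len(h) == pytest.approx(32 / 0.1 + 1, abs=1)

    def test_peak_between_5_and_6_seconds(self):
        dt = 0.01
        h = glm.canonical_hrf(dt)
        t_peak = np.argmax(h) * dt
        assert 5.0 <= t_peak <= 6.0

    def test_undershoot_present(self):
        h = glm.canonical_hrf(0.1)
        assert h.min() < 0  # post-stimulus undershoot
        assert np.argmin(h) > np.argmax(h)


class TestDesign:
    def test_rest_only_run_gives_intercept_only(self):
        ev = pd.DataFrame({"onset": [0.0], "duration": [13.5], "condition": [-1]})
        sched = synthgen.TrialSchedule((ev,), 110, 2.72, 4)
        (dm,) = glm.build_design(sched)
        assert dm.labels == ("intercept",)

    def test_regressor_support_follows_trial(self):
        ev = pd.DataFrame({"onset": [27.0], "duration": [13.5], "condition": [0]})
        sched = synthgen.TrialSchedule((ev,), 110, 2.72, 4)
        (dm,) = glm.build_design(sched)
        reg = dm.matrix[:, 0]
        t_vol = np.arange(110) * 2.72
        assert np.all(np.abs(reg[t_vol < 27.0]) < 1e-9)
        active = np.flatnonzero(np.abs(reg) > 1e-6 * np.abs(reg).max())
        # support spans roughly boxcar + hrf length after onset
        assert t_vol[active[-1]] < 27.0 + 13.5 + 32.0 + 2.72
        assert t_vol[active[-1]] > 27.0 + 13.5

    def test_noiseless_round_trip_unit_coefficient(self):
        sched = sm.make_schedule(n_runs=1, rng_seed=0)
        (dm,) = glm.build_design(sched)
        y = dm.matrix[:, :1] * 3.5  # condition-0 regressor scaled by 3.5
        bp = glm.estimate_betas([y], [dm])
        assert bp.betas[0, 0, 0] == pytest.approx(3.5, abs=1e-10)
        assert abs(bp.betas[1, 0, 0]) < 1e-10

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            glm.DesignMatrix(np.ones((10, 2)), ("a", "a"))

    def test_all_zero_regressor_rejected(self):
        m = np.ones((10, 2))
        m[:, 1] = 0
        with pytest.raises(ValueError):
            glm.DesignMatrix(m, ("a", "b"))


class TestHighpass:
    def test_constant_series_removed(self):
        y = np.full((110, 3), 7.0)
        out = glm.highpass_filter(y, 2.72)
        assert np.abs(out).max() < 1e-10

    def test_linear_drift_mostly_removed(self):
        drift = np.linspace(0, 10, 110)[:, None]
        out = glm.highpass_filter(drift, 2.72)
        assert np.sum(out**2) / np.sum(drift**2) < 0.01

    def test_fast_signal_untouched(self):
        t = np.arange(110) * 2.72
        fast = np.sin(2 * np.pi * 0.1 * t)[:, None]  # 0.1 Hz >> 1/128 Hz
        out = glm.highpass_filter(fast, 2.72)
        assert np.sum((out - fast) ** 2) / np.sum(fast**2) < 0.01

    def test_filter_fit_commutes_with_fitting_filtered(self):
        # residualizing data and design separately equals fitting after
        # projecting both: check betas agree between the two orders
        sched = sm.make_schedule(n_runs=1, rng_seed=1)
        gt = sm.make_ground_truth(10, 1.0, 0.5, 0.0, 0.1, d=2, rng_seed=2)
        y = sm.simulate_timeseries(gt, sched, noise_sd=0.5, rng_seed=3)[0]
        (dm,) = glm.build_design(sched)
        yf = glm.highpass_filter(y, sched.tr)
        xf = glm.highpass_filter(dm.matrix[:, :-1], sched.tr)
        dmf = glm.DesignMatrix(
            np.column_stack([xf, np.ones(len(xf))]), dm.labels
        )
        b1 = glm.estimate_betas([yf], [dmf]).betas
        b2 = glm.fit_glm([y], sched).betas
        np.testing.assert_allclose(b1, b2, atol=1e-8)


class TestEstimateBetas:
    def test_ols_equals_normal_equations_oracle(self, rng):
        sched = sm.make_schedule(n_runs=2, rng_seed=4)
        designs = glm.build_design(sched)
        runs = [rng.normal(size=(110, 7)) for _ in range(2)]
        bp = glm.estimate_betas(runs, designs)
        for r, (y, dm) in enumerate(zip(runs, designs)):
            x = dm.matrix
            oracle = np.linalg.inv(x.T @ x) @ x.T @ y
            np.testing.assert_allclose(bp.betas[:, r, :], oracle[:-1], atol=1e-8)

    def test_rank_deficient_design_raises(self):
        x = np.ones((20, 2))
        dm = glm.DesignMatrix.__new__(glm.DesignMatrix)
        object.__setattr__(dm, "matrix", x)
        object.__setattr__(dm, "labels", ("a", "intercept"))
        with pytest.raises(ValueError, match="rank"):
            glm.estimate_betas([np.ones((20, 2))], [dm])

    def test_robust_downweights_artifact_volume(self):
        sched = sm.make_schedule(n_runs=1, rng_seed=5)
        gt = sm.make_ground_truth(30, 1.0, 0.5, 0.0, 0.0, d=2, rng_seed=6)
        y = sm.simulate_timeseries(gt, sched, noise_sd=0.2, rng_seed=7)[0]
        y_bad = y.copy()
        y_bad[40] += 50.0  # one massive artifact image
        designs = glm.build_design(sched)
        truth = gt.common[None, None, :] + gt.specific[:, None, :]
        err_ols = np.sum((glm.estimate_betas([y_bad], designs).betas - truth) ** 2)
        err_rob = np.sum(
            (glm.estimate_betas([y_bad], designs, robust=True).betas - truth) ** 2
        )
        assert err_rob < err_ols


class TestFIR:
    def test_single_trial_bins_disjoint(self):
        ev = pd.DataFrame({"onset": [27.2], "duration": [13.5], "condition": [0]})
        sched = synthgen.TrialSchedule((ev,), 110, 2.72, 4)
        (dm,) = glm.build_fir_design(sched)
        bins = dm.matrix[:, :-1]
        assert bins.shape[1] == 9
        assert np.all(bins.sum(axis=1) <= 1 + 1e-9)  # single-TR disjoint support
        # summing the 9 bins gives a 9-TR boxcar from onset
        total = bins.sum(axis=1)
        assert total.sum() == pytest.approx(9, abs=1)

    def test_fir_round_trip_on_fir_generated_data(self, rng):
        sched = sm.make_schedule(n_runs=1, rng_seed=8)
        (dm,) = glm.build_fir_design(sched)
        true_amp = rng.normal(size=dm.matrix.shape[1] - 1)
        y = dm.matrix[:, :-1] @ true_amp[:, None] + 2.0
        fir = glm.estimate_fir([y], [dm], n_conditions=4)
        est = fir[:, 0, :, 0].reshape(-1)
        np.testing.assert_allclose(est, true_amp, atol=1e-8)

    def test_fir_tracks_canonical_response_shape(self):
        # data generated with the canonical HRF: the mean FIR time course
        # should correlate strongly with the convolved trial response
        gt = sm.make_ground_truth(8, 1.0, 0.0, 0.0, 0.0, d=1, rng_seed=9)
        sched = sm.make_schedule(n_runs=2, rng_seed=10)
        runs = sm.simulate_timeseries(gt, sched, noise_sd=0.0)
        fir = glm.estimate_fir(runs, glm.build_fir_design(sched), n_conditions=4)
        reg = glm.trial_regressor(0.0, 13.5, 2.72, 30)[:9]
        for v in range(8):
            course = fir[:, :, :, v].mean(axis=(0, 1))
            r = np.corrcoef(course, np.sign(gt.common[v]) * reg)[0, 1]
            assert r > 0.95


class TestTemporalComponents:
    def _fir_from_course(self, course, n_obs=8, n_vox=12, seed=0):
        rng = np.random.default_rng(seed)
        weights = rng.normal(size=(n_obs, n_vox))
        data = np.einsum("b,ov->obv", course, weights)  # (obs, bins, vox)
        return data.reshape(2, n_obs // 2, len(course), n_vox)

    def test_recovers_single_time_course(self):
        course = glm.trial_regressor(0.0, 13.5, 2.72, 9)
        fir = self._fir_from_course(course)
        tc = glm.temporal_components(fir, n_components=3)
        r = abs(np.corrcoef(tc.timecourses[:, 0], course)[0, 1])
        assert r > 0.99

    def test_components_orthonormal_and_ordered(self, rng):
        fir = rng.normal(size=(4, 8, 9, 15))
        tc = glm.temporal_components(fir, n_components=4)
        gram = tc.timecourses.T @ tc.timecourses
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-10)
        assert np.all(np.diff(tc.singular_values) <= 1e-12)

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError):
            glm.temporal_components(np.zeros((2, 2, 9, 4)))


class TestNormalizeTimecourse:
    def test_single_series_unit_norm(self, rng):
        s = rng.normal(size=(1, 9))
        out = glm.normalize_timecourse(s)
        assert np.linalg.norm(out.mean(axis=0)) == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        s = rng.normal(size=(5, 9))
        np.testing.assert_allclose(
            glm.normalize_timecourse(10 * s), glm.normalize_timecourse(s)
        )

    def test_identical_series_normalized_identically(self):
        s = np.tile(np.arange(1.0, 10.0), (2, 1))
        out = glm.normalize_timecourse(s)
        np.testing.assert_allclose(out[0], out[1])

    def test_zero_average_raises(self):
        s = np.array([[1.0, -1.0], [-1.0, 1.0]])
        with pytest.raises(ValueError):
            glm.normalize_timecourse(s)
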