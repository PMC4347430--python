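import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fragilenet.detector import (
    CalibrationError,
    DetectorParams,
    EmissionModel,
    FiringRateSeries,
    Gaussian,
    OnlineDetector,
    calibrate_max_count,
    calibrate_threshold,
    detect_stability,
    firing_rate_series,
    fit_emissions,
    instability_statistic,
    likelihood_ratio,
)
from fragilenet.network import NetworkConfig, NetworkTrace, gillespie_simulate


def _params(**kw):
    defaults = dict(m=250.0, n=25, grid_dt=1.0, max_count=10)
    defaults.update(kw)
    return DetectorParams(**defaults)


def _series(p_values, grid_dt=1.0, start=274.0):
    p = np.asarray(p_values, dtype=float)
    return FiringRateSeries(
        times=start + grid_dt * np.arange(p.size),
        p=p,
        grid_dt=grid_dt,
        exceeded=np.zeros(p.size, dtype=bool),
    )


class TestFiringRateSeries:
    def test_no_spikes_is_zero(self):
        series = firing_rate_series(np.array([]), 1, _params(), 5_000.0)
        assert np.all(series.p == 0.0)
        assert series.times[0] == pytest.approx(274.0)  # m + (n-1) * grid_dt

    def test_every_window_at_max_count_gives_one(self):
        # period-25 train: every 250 ms window holds exactly 10 spikes
        spikes = np.arange(12.5, 10_000.0, 25.0)
        series = firing_rate_series(spikes, 1, _params(max_count=10), 10_000.0)
        np.testing.assert_allclose(series.p, 1.0)

    def test_regular_train_settles_at_count_over_max(self):
        # period m/k with k = 5 -> every window holds 5 spikes -> p = 5/10
        spikes = np.arange(25.0, 20_000.0, 50.0)
        series = firing_rate_series(spikes, 1, _params(), 20_000.0)
        np.testing.assert_allclose(series.p, 0.5)

    def test_too_short_duration_raises(self):
        with pytest.raises(ValueError, match="burn-in"):
            firing_rate_series(np.array([1.0]), 1, _params(), 260.0)

    def test_exceeded_flag_without_clipping(self):
        spikes = np.sort(np.random.default_rng(0).uniform(0, 3_000.0, 300))
        series = firing_rate_series(spikes, 1, _params(max_count=3), 3_000.0)
        assert series.exceeded.any()
        assert series.p.max() > 1.0  # flagged, not clipped

    @given(st.integers(0, 2**31 - 1), st.integers(1, 200))
    @settings(max_examples=20, deadline=None)
    def test_matches_brute_force_counting(self, seed, n_spikes):
        params = _params(m=100.0, n=5, max_count=4)
        duration = 1_000.0
        spikes = np.sort(np.random.default_rng(seed).uniform(0, duration, n_spikes))
        series = firing_rate_series(spikes, 1, params, duration)
        for idx in (0, len(series.times) // 2, len(series.times) - 1):
            t = series.times[idx]
            expected = np.mean(
                [
                    np.sum((spikes > w - 100.0) & (spikes <= w)) / 4.0
                    for w in t - np.arange(5)
                ]
            )
            assert series.p[idx] == pytest.approx(expected)


class TestCalibrateMaxCount:
    def test_known_densest_window(self):
        # densest 250 ms window holds 7 spikes; exhaustive scan agrees
        spikes = np.concatenate(
            [np.linspace(1_000.0, 1_200.0, 7), np.arange(2_000.0, 9_000.0, 400.0)]
        )
        trace = NetworkTrace(
            event_times=spikes,
            states=None,
            spike_times=[np.sort(spikes)],
            duration=10_000.0,
        )
        params = _params(max_count=None)
        cfg = NetworkConfig(weights=np.zeros((1, 1)), h=np.array([0.5]))
        got = calibrate_max_count(cfg, params, node=1, trace=trace)
        brute = max(
            np.sum((spikes > t - 250.0) & (spikes <= t))
            for t in np.arange(250.0, 10_000.0, 1.0)
        )
        assert got == brute == 7

    def test_longer_calibration_never_decreases(self, modes):
        params = _params(max_count=None)
        trace = gillespie_simulate(modes.cfg, 30_000.0, seed=21, record_states=False)
        short = NetworkTrace(
            event_times=trace.event_times,
            states=None,
            spike_times=[sp[sp < 10_000.0] for sp in trace.spike_times],
            duration=10_000.0,
        )
        node = 4
        assert calibrate_max_count(modes.cfg, params, node=node, trace=trace) >= (
            calibrate_max_count(modes.cfg, params, node=node, trace=short)
        )

    def test_reproducible_for_fixed_seed(self, modes):
        params = _params(max_count=None)
        a = calibrate_max_count(modes.cfg, params, node=4, duration=10_000.0, seed=9)
        b = calibrate_max_count(modes.cfg, params, node=4, duration=10_000.0, seed=9)
        assert a == b >= 1

    def test_zero_spikes_errors(self):
        trace = NetworkTrace(
            event_times=np.array([]),
            states=None,
            spike_times=[np.array([])],
            duration=10_000.0,
        )
        cfg = NetworkConfig(weights=np.zeros((1, 1)), h=np.array([0.5]))
        with pytest.raises(CalibrationError, match="no spikes"):
            calibrate_max_count(cfg, _params(max_count=None), node=1, trace=trace)


class TestFitEmissions:
    def test_hand_mle(self):
        em = fit_emissions(np.array([0.2, 0.4]), np.array([0.2, 0.4]))
        assert em.q1.mean == pytest.approx(0.3)
        assert em.q1.var == pytest.approx(0.01)  # biased 1/N variance

    def test_parameter_recovery_within_3_se(self, rng):
        n = 10_000
        mu, sd = 0.4, 0.07
        draws = rng.normal(mu, sd, n)
        em = fit_emissions(draws, draws)
        se_mean = sd / np.sqrt(n)
        se_var = sd**2 * np.sqrt(2.0 / n)
        assert abs(em.q1.mean - mu) < 3 * se_mean
        assert abs(em.q1.var - sd**2) < 3 * se_var

    def test_identical_samples_give_identical_densities(self, rng):
        x = rng.random(50)
        em = fit_emissions(x, x)
        assert em.q1 == em.q2

    def test_zero_variance_errors(self):
        with pytest.raises(CalibrationError, match="zero variance"):
            fit_emissions(np.array([0.3, 0.3, 0.3]), np.array([0.1, 0.2]))

    def test_variance_floor_rescues_constant_mode(self):
        em = fit_emissions(
            np.array([0.1, 0.2]), np.zeros(100), var_floor=1e-4
        )
        assert em.q2.mean == 0.0
        assert em.q2.var == 1e-4

    def test_too_few_samples(self):
        with pytest.raises(CalibrationError, match=">= 2 samples"):
            fit_emissions(np.array([0.3]), np.array([0.1, 0.2]))


class TestLikelihoodRatio:
    def test_identical_densities_give_one(self, rng):
        g = Gaussian(0.3, 0.01)
        em = EmissionModel(q1=g, q2=g)
        np.testing.assert_allclose(likelihood_ratio(rng.random(20), em), 1.0)

    def test_midpoint_with_equal_variances(self):
        em = EmissionModel(q1=Gaussian(0.6, 0.01), q2=Gaussian(0.2, 0.01))
        assert likelihood_ratio(0.4, em) == pytest.approx(1.0)

    def test_larger_than_one_at_unstable_mean(self):
        em = EmissionModel(q1=Gaussian(0.6, 0.01), q2=Gaussian(0.2, 0.01))
        assert likelihood_ratio(0.2, em) > 1.0

    def test_always_positive_and_finite(self):
        em = EmissionModel(q1=Gaussian(0.6, 1e-6), q2=Gaussian(0.0, 1e-8))
        for p in (-5.0, 0.0, 0.6, 50.0):
            lr = likelihood_ratio(p, em)
            assert 0.0 < lr < np.inf


class TestInstabilityStatistic:
    def test_gr_strictly_increasing(self, rng):
        em = EmissionModel(q1=Gaussian(0.5, 0.01), q2=Gaussian(0.1, 0.01))
        state = instability_statistic(_series(rng.random(500)), em, _params())
        assert np.all(state.LR > 0)
        # strictly increasing up to float absorption of clamped tiny ratios
        assert np.all(np.diff(state.gr) >= 0)

    def test_dgr_is_lr_over_dt(self, rng):
        em = EmissionModel(q1=Gaussian(0.5, 0.01), q2=Gaussian(0.1, 0.01))
        series = _series(rng.random(100), grid_dt=2.0)
        state = instability_statistic(series, em, _params(grid_dt=2.0))
        np.testing.assert_allclose(state.dgr, state.LR / 2.0)

    def test_step_change_detected_after_onset(self, rng):
        em = EmissionModel(q1=Gaussian(0.5, 0.002), q2=Gaussian(0.1, 0.002))
        p = np.concatenate(
            [
                rng.normal(0.5, 0.04, 1000),
                rng.normal(0.1, 0.04, 1000),
            ]
        )
        series = _series(p)
        t_star = series.times[1000]
        params = _params(threshold=likelihood_ratio(0.3, em))
        state = instability_statistic(series, em, params)
        assert state.unstable_detection_time is not None
        assert state.unstable_detection_time >= t_star

    def test_no_detection_on_stable_draws(self, calib, modes):
        trace = gillespie_simulate(modes.cfg, 60_000.0, seed=33, record_states=False)
        series = firing_rate_series(trace.spike_times, calib.node, calib.params, 60_000.0)
        state = instability_statistic(series, calib.emissions, calib.params)
        assert state.unstable_detection_time is None


class TestCalibrateThreshold:
    def test_pooling_is_symmetric(self, modes, calib):
        cfgs = [modes.unstable_config(0.0), modes.unstable_config(200.0)]
        kw = dict(
            em=calib.emissions,
            params=calib.params,
            node=calib.node,
            duration=10_000.0,
        )
        a = calibrate_threshold(cfgs, seeds=[5, 6], **kw)
        b = calibrate_threshold(cfgs[::-1], seeds=[6, 5], **kw)
        assert a == pytest.approx(b)

    def test_reproducible_with_fixed_seeds(self, modes, calib):
        cfgs = [modes.unstable_config(200.0)]
        kw = dict(
            em=calib.emissions,
            params=calib.params,
            node=calib.node,
            duration=10_000.0,
            seeds=[5],
        )
        assert calibrate_threshold(cfgs, **kw) == calibrate_threshold(cfgs, **kw)

    def test_constant_dgr_errors(self):
        # a silent node yields p identically zero -> constant LR -> degenerate
        p = DetectorParams(max_count=5)
        cfg = NetworkConfig(
            weights=np.zeros((1, 1)),
            h=np.array([-5.0]),
        )
        em = EmissionModel(q1=Gaussian(0.5, 0.01), q2=Gaussian(0.1, 0.01))
        with pytest.raises(CalibrationError, match="degenerate"):
            calibrate_threshold([cfg], em, p, node=1, duration=2_000.0, seeds=[0])


class TestDetectStability:
    EM = EmissionModel(q1=Gaussian(0.5, 0.0025), q2=Gaussian(0.1, 0.0025))  # sd1 = 0.05

    def test_constant_at_mean_detects_after_hold(self):
        series = _series(np.full(2000, 0.5))
        t = detect_stability(series, self.EM, _params())
        # first grid point >= entry + stable_hold
        assert t == pytest.approx(series.times[0] + 500.0)

    def test_outside_band_never_detects(self):
        series = _series(np.full(2000, 0.5 + 3 * 0.05))
        assert detect_stability(series, self.EM, _params()) is None

    def test_band_endpoints_inclusive(self):
        series = _series(np.full(2000, 0.5 + 2 * 0.05))
        assert detect_stability(series, self.EM, _params()) is not None

    def test_exit_resets_hold_timer(self):
        p = np.full(2000, 0.5)
        p[499] = 0.9  # leaves the band 499 ms after entry
        series = _series(p)
        t = detect_stability(series, self.EM, _params())
        assert t == pytest.approx(series.times[500] + 500.0)

    def test_start_time_ignores_earlier_samples(self):
        p = np.full(2000, 0.5)
        series = _series(p)
        t = detect_stability(series, self.EM, _params(), start_time=series.times[700])
        assert t == pytest.approx(series.times[700] + 500.0)


class TestOnlineDetector:
    def test_matches_offline_pipeline(self, rng):
        params = _params(threshold=10.0)
        em = EmissionModel(q1=Gaussian(0.5, 0.01), q2=Gaussian(0.2, 0.01))
        duration = 3_000.0
        spikes = np.sort(rng.uniform(0, duration, 400))
        online = OnlineDetector(params, em)
        for t_spike in spikes:
            online.add_spike(t_spike)
        ps, lrs, grs = [], [], []
        for k in range(1, int(duration) + 1):
            online.update(float(k))
            if online.ready:
                ps.append(online.p)
                lrs.append(online.LR)
                grs.append(online.gr)
        series = firing_rate_series(spikes, 1, params, duration)
        state = instability_statistic(series, em, params)
        np.testing.assert_allclose(ps, state.p, atol=1e-12)
        # ulp-level differences in p are amplified through the exponent
        np.testing.assert_allclose(lrs, state.LR, rtol=1e-8)
        np.testing.assert_allclose(grs, state.gr, rtol=1e-8)

    def test_requires_calibration(self):
        em = EmissionModel(q1=Gaussian(0.5, 0.01), q2=Gaussian(0.2, 0.01))
        with pytest.raises(CalibrationError):
            OnlineDetector(DetectorParams(), em)
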