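"""Generator correctness: waiting-time law, controls, modulated channels."""
import numpy as np
import pytest

from csync import synthgen
from csync.synthgen import ModulationSpec, RenewalSpec
from csync.types import EventTrain


class TestWaitingTimes:
    def test_mean_matches_lomax_closed_form(self):
        # for mu > 2 the mean is T / (mu - 2)
        spec = RenewalSpec(mu=2.5, n_events=10**6, T=1.0, seed=1)
        w = synthgen.sample_waiting_times(spec)
        assert np.all(w >= 0)
        assert w.mean() == pytest.approx(2.0, rel=0.05)

    def test_median_matches_inverse_cdf(self):
        # median = T * (2**(1/(mu-1)) - 1); equals T at mu = 2
        spec = RenewalSpec(mu=2.0, n_events=10**6, T=1.0, seed=1)
        w = synthgen.sample_waiting_times(spec)
        assert np.median(w) == pytest.approx(1.0, rel=0.02)

    def test_empty_draw(self):
        assert synthgen.sample_waiting_times(RenewalSpec(mu=2.5, n_events=0)).size == 0

    @pytest.mark.parametrize("mu", [0.9, 1.0, 3.0, 3.5])
    def test_mu_domain_error(self, mu):
        with pytest.raises(ValueError):
            RenewalSpec(mu=mu, n_events=10)

    def test_invalid_scale_and_rule(self):
        with pytest.raises(ValueError):
            RenewalSpec(mu=2.5, n_events=10, T=0.0)
        with pytest.raises(ValueError):
            RenewalSpec(mu=2.5, n_events=10, rule="sideways")

    @pytest.mark.parametrize("mu", [1.5, 2.5])
    def test_survival_tail_slope(self, mu):
        # log-log survival slope approaches -(mu - 1)
        spec = RenewalSpec(mu=mu, n_events=10**6, seed=1)
        w = np.sort(synthgen.sample_waiting_times(spec))
        surv = 1.0 - np.arange(w.size) / w.size
        # fit the tail between the 99th and 99.99th percentiles
        m = (surv < 1e-2) & (surv > 1e-4) & (w > 0)
        slope = np.polyfit(np.log(w[m]), np.log(surv[m]), 1)[0]
        assert slope == pytest.approx(-(mu - 1.0), abs=0.1)

    def test_running_mean_diverges_below_mu_two(self):
        # infinite-mean regime: the empirical mean grows without bound as
        # the sample deepens, unlike the convergent mu > 2 case
        w = synthgen.sample_waiting_times(RenewalSpec(mu=1.5, n_events=10**6, seed=1))
        assert w.mean() / w[: 10**3].mean() > 10
        v = synthgen.sample_waiting_times(RenewalSpec(mu=2.5, n_events=10**6, seed=1))
        assert 0.8 < v.mean() / v[: 10**4].mean() < 1.25

    def test_seed_determinism(self):
        spec = RenewalSpec(mu=2.5, n_events=1000, seed=42)
        assert np.array_equal(
            synthgen.sample_waiting_times(spec), synthgen.sample_waiting_times(spec)
        )


class TestEventsFromWaits:
    def test_cumulative_rounding(self):
        train = synthgen.events_from_waits([2.2, 3.1, 4.0])
        assert train.indices.tolist() == [2, 5, 9]

    def test_collisions_merge(self):
        train = synthgen.events_from_waits([0.2, 0.2])
        assert train.n_events == 1

    def test_empty(self):
        assert synthgen.events_from_waits([]).n_events == 0

    def test_negative_waits_rejected(self):
        with pytest.raises(ValueError):
            synthgen.events_from_waits([1.0, -0.5])


class TestStepSignal:
    def test_jump_ahead_definition(self):
        train = EventTrain(np.array([2, 5]), length=8)
        sig = synthgen.make_step_signal(train, 8, "jump_ahead")
        assert sig.data.tolist() == [0, 0, 1, 0, 0, 1, 0, 0]

    def test_velocity_no_events_is_constant(self):
        train = EventTrain(np.array([], dtype=np.int64), length=5)
        sig = synthgen.make_step_signal(train, 5, "velocity_pm1", seed=3)
        assert np.all(np.abs(sig.data) == 1.0)
        assert np.unique(sig.data).size == 1

    def test_impulse_nonzeros_equal_event_count(self):
        train = EventTrain(np.array([1, 4, 7, 9]), length=12)
        sig = synthgen.make_step_signal(train, 12, "impulse_at_event", seed=0)
        assert np.count_nonzero(sig.data) == 4
        assert set(np.unique(sig.data[sig.data != 0])) <= {-1.0, 1.0}

    def test_unknown_rule(self):
        train = EventTrain(np.array([1]), length=4)
        with pytest.raises(ValueError):
            synthgen.make_step_signal(train, 4, "warp")


class TestFBM:
    def test_brownian_limit_uncorrelated(self):
        rng = np.random.default_rng(1)
        x = synthgen.fgn(0.5, 10**5, rng)
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r1) < 0.01

    def test_fgn_lag_one_autocorrelation(self):
        # closed form: rho(1) = 2**(2H-1) - 1
        rng = np.random.default_rng(1)
        x = synthgen.fgn(0.75, 10**5, rng)
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert r1 == pytest.approx(2 ** (2 * 0.75 - 1) - 1, abs=0.02)

    def test_determinism(self):
        a = synthgen.gen_fbm(0.7, 4096, seed=9)
        b = synthgen.gen_fbm(0.7, 4096, seed=9)
        assert np.array_equal(a.data, b.data)

    @pytest.mark.parametrize("H", [0.0, 1.0, -0.2, 1.3])
    def test_hurst_domain(self, H):
        with pytest.raises(ValueError):
            synthgen.gen_fbm(H, 100, seed=0)


class TestPoisson:
    def test_event_count(self):
        # on a discrete sample grid coincident arrivals merge, so the
        # expected count is length * (1 - exp(-rate))
        train = synthgen.gen_poisson_train(0.1, 10**6, seed=1)
        p = 1.0 - np.exp(-0.1)
        expected = 10**6 * p
        sigma = np.sqrt(10**6 * p * (1 - p))
        assert abs(train.n_events - expected) < 3 * sigma

    def test_short_series_can_be_empty(self):
        train = synthgen.gen_poisson_train(1e-4, 10, seed=1)
        assert train.n_events in (0, 1)

    def test_rate_domain(self):
        with pytest.raises(ValueError):
            synthgen.gen_poisson_train(0.0, 100)


class TestModulatedChannels:
    def test_zero_amplitude_flat_ground_truth(self):
        mod = ModulationSpec(amplitude=0.0, channel_jitter_sd=0.0)
        _, gt = synthgen.gen_modulated_channels(mod, 1, 30.0, 100.0, seed=1)
        assert np.allclose(gt.shared_delta, gt.shared_delta[0])
        assert np.allclose(gt.delta, gt.shared_delta[None, :])

    def test_zero_jitter_identical_ground_truth(self):
        mod = ModulationSpec(channel_jitter_sd=0.0)
        _, gt = synthgen.gen_modulated_channels(mod, 2, 30.0, 100.0, seed=1)
        assert np.allclose(gt.delta[0], gt.delta[1])
        from csync.csreport import cross_correlation
        assert cross_correlation(gt.delta[0], gt.delta[1]) == pytest.approx(1.0)

    def test_ground_truth_oscillation_range(self):
        # mu in [2.2, 2.8] maps to delta in [1/1.8, 1/1.2]
        mod = ModulationSpec(mu_base=2.5, amplitude=0.3, channel_jitter_sd=0.0)
        _, gt = synthgen.gen_modulated_channels(mod, 1, 240.0, 100.0, seed=1)
        assert gt.shared_delta.min() == pytest.approx(1 / 1.8, abs=0.01)
        assert gt.shared_delta.max() == pytest.approx(1 / 1.2, abs=0.01)

    def test_modulation_domain_error(self):
        with pytest.raises(ValueError):
            ModulationSpec(mu_base=2.8, amplitude=0.3)

    def test_telegraph_signal_and_determinism(self):
        mod = ModulationSpec()
        sig, _ = synthgen.gen_modulated_channels(mod, 2, 20.0, 100.0, seed=5)
        assert set(np.unique(sig.data)) <= {-1.0, 1.0}
        sig2, _ = synthgen.gen_modulated_channels(mod, 2, 20.0, 100.0, seed=5)
        assert np.array_equal(sig.data, sig2.data)
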