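"""Diffusion entropy analysis: trajectories, entropy curves, scaling fits."""
import numpy as np
import pytest

from csync import dea, synthgen
from csync.synthgen import RenewalSpec
from csync.types import DiffusionTrajectory, EntropyCurve, EventTrain, RawSignal


class TestBuildTrajectory:
    def test_jump_ahead_cumulative_count(self):
        train = EventTrain(np.array([2, 5, 9]), length=10)
        X = dea.build_trajectory(train, rule="jump_ahead")
        assert X.samples.tolist() == [0, 0, 1, 1, 1, 2, 2, 2, 2, 3]

    def test_no_events_flat(self):
        train = EventTrain(np.array([], dtype=np.int64), length=6)
        X = dea.build_trajectory(train, rule="jump_ahead")
        assert np.all(X.samples == 0)

    def test_velocity_reproducible(self):
        train = EventTrain(np.array([3, 8, 15]), length=20)
        a = dea.build_trajectory(train, rule="velocity_pm1", seed=5)
        b = dea.build_trajectory(train, rule="velocity_pm1", seed=5)
        assert np.array_equal(a.samples, b.samples)

    def test_unknown_rule(self):
        with pytest.raises(ValueError):
            dea.build_trajectory(EventTrain(np.array([1]), length=4), rule="hop")


class TestEntropyCurve:
    def test_ballistic_zero_entropy(self):
        traj = DiffusionTrajectory(np.arange(2000, dtype=float), "ballistic")
        curve = dea.entropy_curve(traj)
        assert np.allclose(curve.entropy[curve.valid], 0.0, atol=1e-12)

    def test_brownian_pm1_slope_half(self):
        rng = np.random.default_rng(1)
        traj = DiffusionTrajectory(np.cumsum(rng.choice([-1.0, 1.0], 10**5)), "pm1")
        est = dea.fit_scaling(dea.entropy_curve(traj))
        assert est.delta == pytest.approx(0.5, abs=0.02)

    def test_amplitude_scaling_with_proportional_bins(self):
        rng = np.random.default_rng(2)
        X = np.cumsum(rng.normal(size=20000))
        w = np.array([16, 32, 64, 128, 256])
        a = dea.entropy_curve(DiffusionTrajectory(X, "g"), w_grid=w, bin_width=0.25)
        b = dea.entropy_curve(DiffusionTrajectory(2 * X, "g"), w_grid=w, bin_width=0.5)
        # differential entropy shifts by ln 2 under doubling; the +ln(h)
        # convention makes the curves differ by exactly that constant
        assert np.allclose(b.entropy - a.entropy, np.log(2.0), atol=0.02)

    def test_time_reversal_invariance(self):
        rng = np.random.default_rng(3)
        inc = rng.choice([-1.0, 1.0], 20000)
        w = np.array([8, 16, 32, 64])
        a = dea.entropy_curve(DiffusionTrajectory(np.cumsum(inc), "pm1"), w_grid=w)
        b = dea.entropy_curve(DiffusionTrajectory(np.cumsum(inc[::-1]), "pm1"), w_grid=w)
        assert np.allclose(a.entropy, b.entropy, atol=0.02)

    def test_min_subwindows_flags_missing(self):
        traj = DiffusionTrajectory(np.arange(400, dtype=float), "b")
        curve = dea.entropy_curve(traj, w_grid=[4, 8, 16], min_subwindows=10**6)
        assert np.all(~curve.valid)

    def test_window_bounds_checked(self):
        traj = DiffusionTrajectory(np.arange(100, dtype=float), "b")
        with pytest.raises(ValueError):
            dea.entropy_curve(traj, w_grid=[2, 90])


class TestFitScaling:
    def test_exact_line(self):
        w = np.logspace(1, 3, 12)
        curve = EntropyCurve(w, 1.0 + 0.6 * np.log(w), np.full(12, 1000))
        est = dea.fit_scaling(curve, fit_range=(w[0], w[-1]))
        assert est.delta == pytest.approx(0.600, abs=1e-12)
        assert est.r2 == pytest.approx(1.0)
        assert est.admissible

    def test_too_few_points(self):
        w = np.array([10.0, 20.0, 40.0])
        curve = EntropyCurve(w, np.log(w), np.full(3, 100))
        with pytest.raises(ValueError):
            dea.fit_scaling(curve, fit_range=(10, 40))

    def test_negative_slope_flagged(self):
        w = np.logspace(1, 2, 8)
        curve = EntropyCurve(w, -0.2 * np.log(w), np.full(8, 100))
        est = dea.fit_scaling(curve, fit_range=(w[0], w[-1]))
        assert not est.admissible


class TestRenewalScaling:
    def test_monotone_complexity_ordering(self):
        """Estimated delta decreases as mu increases (ergodic branch)."""
        from csync.recovery import recover_delta_ergodic

        deltas = [
            recover_delta_ergodic(mu, n_events=50_000, n_realizations=4, seed=1)
            for mu in (2.2, 2.5, 2.8)
        ]
        assert deltas[0] > deltas[1] > deltas[2]

    def test_pdf_collapse_oracle_agrees_with_entropy_slope(self):
        """Quantile collapse of P(x, w) under x/w^delta matches the
        entropy slope.

        The oracle reads delta directly from how the centred displacement
        quantiles widen with w — no entropy involved.  Both statistics are
        taken as medians over independent realizations, which suppresses
        the heavy-tailed single-record fluctuations.
        """
        e_grid = np.logspace(np.log10(20), np.log10(2000), 12)
        qs = np.arange(0.1, 0.91, 0.1)
        S_all, Q_all = [], []
        ss = np.random.SeedSequence([1, 0x5E])
        from csync.striping import StripeConfig, extract_events

        for child in ss.spawn(6):
            rng = np.random.default_rng(child)
            waits = rng.random(10**5) ** (-1.0 / 1.5) - 1.0  # mu = 2.5
            train = synthgen.events_from_waits(waits)
            sig = synthgen.make_step_signal(
                train, train.length, "velocity_pm1", seed=int(rng.integers(2**31))
            )
            ext = extract_events(sig, StripeConfig(1.0))
            X = dea.build_trajectory(ext, rule="jump_ahead").samples
            tau = ext.length / ext.n_events
            wg = np.maximum(2, np.round(e_grid * tau)).astype(int)
            curve = dea.entropy_curve(DiffusionTrajectory(X, "j"), w_grid=np.unique(wg))
            S_all.append(
                np.interp(np.log(e_grid * tau), np.log(curve.window_sizes), curve.entropy)
            )
            qrow = []
            for w in wg:
                disp = X[w:] - X[:-w]
                c = disp - np.median(disp)
                qrow.append(np.log(np.quantile(np.abs(c), qs)).mean())
            Q_all.append(qrow)
        x = np.log(e_grid)
        d_entropy = np.polyfit(x, np.median(S_all, axis=0), 1)[0]
        d_collapse = np.polyfit(x, np.median(Q_all, axis=0), 1)[0]
        assert d_entropy == pytest.approx(d_collapse, abs=0.05)


class TestFBMScaling:
    @pytest.mark.parametrize("H", [0.3, 0.6, 0.75])
    def test_delta_equals_hurst(self, H):
        sig = synthgen.gen_fbm(H, 10**5, seed=1)
        curve = dea.entropy_curve(DiffusionTrajectory(sig.data, "fbm"))
        est = dea.fit_scaling(curve, fit_range=(10, 1000))
        assert est.delta == pytest.approx(H, abs=0.05)


class TestShuffle:
    def test_poisson_memoryless_in_both_orders(self):
        train = synthgen.gen_poisson_train(0.1, 10**6, seed=1)
        d0, d1 = dea.shuffle_test(train, seed=1)
        assert d0 == pytest.approx(0.5, abs=0.05)
        assert d1 == pytest.approx(0.5, abs=0.05)

    def test_fbm_collapses_to_half(self):
        sig = synthgen.gen_fbm(0.75, 10**5, seed=1)
        d0, d1 = dea.shuffle_test(sig, seed=1)
        assert d0 == pytest.approx(0.75, abs=0.08)  # long-memory path
        assert d1 == pytest.approx(0.5, abs=0.05)  # permuted increments
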