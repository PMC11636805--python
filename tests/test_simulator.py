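import numpy as np
import pytest

from causalflow.datatypes import EnsembleTimeSeries, NoiseSpec, PerturbationSession, SimulatorParams
from causalflow.simulator import (
    inject_noise,
    make_trial_onsets,
    poissonify,
    run_perturbation_session,
    simulate_network,
)


class TestSimulateNetwork:
    def test_network_has_103_units(self, short_run):
        assert short_run.values.shape[0] == 103
        assert short_run.unit_ids[:3] == ["x1", "x2", "x3"]
        assert short_run.subnetwork_labels.count("Y") == 100

    def test_reproducible_bit_exact(self, short_params, short_run):
        again = simulate_network(short_params)
        assert np.array_equal(short_run.values, again.values)

    def test_pure_leak_decays_to_zero(self):
        p = SimulatorParams(g=0.0, g_r=0.0, I=0.0, sigma_dyn=0.0, n_y=10, duration=40.0, transient=0.0, seed=2)
        ts = simulate_network(p)
        tail = ts.values[3:, -ts.n_samples // 10 :]
        assert np.abs(tail).max() < 1e-6

    def test_divergence_raises_named_error(self):
        p = SimulatorParams(alpha=2.0, n_y=2, duration=100.0, transient=0.0, sigma_dyn=0.0, seed=0)
        with pytest.raises(FloatingPointError, match="diverged"):
            simulate_network(p)

    def test_rk4_halving_converges_on_short_horizon(self):
        # chaotic error growth makes long-horizon comparison meaningless; over
        # a short span the 4th-order integrator must agree tightly
        a = simulate_network(SimulatorParams(duration=2.5, transient=0.5, seed=5, sigma_dyn=0.0, dt=0.01))
        b = simulate_network(SimulatorParams(duration=2.5, transient=0.5, seed=5, sigma_dyn=0.0, dt=0.005))
        # recorded columns are post-step states, so the fine run aligns at 1::2
        rms = np.sqrt(np.mean((a.values - b.values[:, 1::2]) ** 2))
        assert rms < 1e-4

    def test_uncoupled_driver_uncorrelated_with_rate_units(self):
        # with g=0 the max lagged X-Y cross-correlation sits at the level of
        # a shuffled-pair null
        p = SimulatorParams(g=0.0, duration=80.0, transient=20.0, seed=9)
        ts = simulate_network(p).bin(0.1)
        rng = np.random.default_rng(0)

        def max_lagged_corr(a, b, lags=50):
            a = (a - a.mean()) / a.std()
            b = (b - b.mean()) / b.std()
            return max(
                abs(np.corrcoef(a[max(l, 0) : len(a) + min(l, 0)], b[max(-l, 0) : len(b) + min(-l, 0)])[0, 1])
                for l in range(-lags, lags + 1)
            )

        x = ts.series("x1")
        stats = [max_lagged_corr(x, ts.values[3 + i]) for i in range(0, 30, 10)]
        null = [
            max_lagged_corr(x, np.roll(ts.values[3 + i], int(rng.integers(100, 500))))
            for i in range(0, 30, 10)
            for _ in range(10)
        ]
        assert np.median(stats) <= np.quantile(null, 0.95)


class TestInjectNoise:
    def test_snr_contract_exact(self, short_run):
        for mode in ("private", "shared"):
            noisy = inject_noise(short_run, NoiseSpec(mode=mode, snr_db=7.0, seed=1))
            e = noisy.values - short_run.values
            measured = 10 * np.log10(short_run.values.std(axis=1) / e.std(axis=1))
            assert np.allclose(measured, 7.0, atol=1e-9)

    def test_zero_db_noise_matches_signal_sd(self, short_run):
        noisy = inject_noise(short_run, NoiseSpec(mode="private", snr_db=0.0, seed=1))
        e = noisy.values - short_run.values
        assert np.allclose(e.std(axis=1), short_run.values.std(axis=1))

    def test_shared_noise_perfectly_correlated_across_units(self, short_run):
        noisy = inject_noise(short_run, NoiseSpec(mode="shared", snr_db=5.0, seed=3))
        e = noisy.values - short_run.values
        C = np.corrcoef(e[:5])
        assert np.allclose(np.abs(C), 1.0, atol=1e-12)

    def test_private_noise_uncorrelated_across_units(self, short_run):
        noisy = inject_noise(short_run, NoiseSpec(mode="private", snr_db=5.0, seed=3))
        e = noisy.values - short_run.values
        C = np.corrcoef(e[:10])
        off = C[~np.eye(10, dtype=bool)]
        assert np.abs(off).mean() < 3 / np.sqrt(short_run.n_samples)

    def test_constant_row_rejected(self):
        ts = EnsembleTimeSeries(np.vstack([np.ones(100), np.arange(100.0)]), 0.1, ["a", "b"])
        with pytest.raises(ValueError, match="zero-variance"):
            inject_noise(ts, NoiseSpec(mode="private", snr_db=0.0))


class TestPerturbationSession:
    def _session(self, n_trials=2, **kw):
        onsets = make_trial_onsets(n_trials, record_duration=40.0, seed=0)
        return PerturbationSession(trial_onsets=onsets, **kw)

    def test_zero_strength_pulse_is_bit_identical_to_rest(self, short_params, short_run):
        sess = self._session(stimulated_unit="y10", pulse_strength=0.0)
        rec = run_perturbation_session(short_params, sess)
        assert np.array_equal(rec.values, short_run.values)

    def test_no_feedback_to_driver(self, short_params, short_run):
        # stimulating a Y unit cannot alter the Roessler coordinates
        sess = self._session(stimulated_unit="y10", pulse_strength=20.0)
        rec = run_perturbation_session(short_params, sess)
        assert np.array_equal(rec.values[:3], short_run.values[:3])
        assert not np.array_equal(rec.values[3:], short_run.values[3:])

    def test_driver_stimulation_shifts_rate_unit_distribution(self):
        from causalflow.interventional import extract_windows, ks_statistic

        params = SimulatorParams(n_y=20, duration=150.0, transient=20.0, seed=4)

        def ks_for(strength, seed):
            onsets = make_trial_onsets(8, record_duration=130.0, seed=seed)
            sess = PerturbationSession(stimulated_unit="x1", trial_onsets=onsets, pulse_strength=strength)
            sess.recording = run_perturbation_session(params, sess)
            pre, post = extract_windows(sess, "y4")
            return ks_statistic(pre, post)

        strong = np.mean([ks_for(30.0, s) for s in range(3)])
        null = np.mean([ks_for(0.0, s) for s in range(3)])
        assert strong > null

    def test_out_of_range_onsets_rejected(self, short_params):
        sess = PerturbationSession(stimulated_unit="x1", trial_onsets=np.array([39.5]))
        with pytest.raises(ValueError, match="outside"):
            run_perturbation_session(short_params, sess)

    def test_overlapping_trials_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            PerturbationSession(stimulated_unit="x1", trial_onsets=np.array([5.0, 6.0]))


class TestPoissonify:
    def test_zero_gain_gives_zero_counts(self, short_run):
        counts = poissonify(short_run, gain=0.0, bin_width=0.1, seed=0)
        assert counts.values.sum() == 0

    def test_constant_rate_moments(self):
        # softplus(x) with large x ~ x, so gain * activity is the latent rate
        rate, bin_w, n_bins = 8.0, 0.5, 10_000
        ts = EnsembleTimeSeries(np.full((1, n_bins * 5), 50.0), dt=0.1, unit_ids=["u"])
        counts = poissonify(ts, gain=rate / 50.0, bin_width=bin_w, seed=1).values[0]
        lam = rate * bin_w
        assert abs(counts.mean() - lam) < 4 * np.sqrt(lam / len(counts))
        assert abs(counts.var() / counts.mean() - 1.0) < 0.05

    def test_bin_smaller_than_dt_rejected(self, short_run):
        with pytest.raises(ValueError, match="bin"):
            poissonify(short_run, gain=1.0, bin_width=0.001)
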