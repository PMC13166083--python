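"""Stage-1 artifact estimation: grid, landmarks, interpolation, bridging."""

import numpy as np
import pytest

import loglira as ll
from loglira.config import ms_to_samples
from loglira.estimation import (blank_only, clean_trial, saturation_thresholds)


def brute_moving_average(x, window):
    """Independent centered moving average with shrinking edges."""
    half = window // 2
    out = np.empty_like(x, dtype=float)
    for n in range(x.size):
        lo, hi = max(0, n - half), min(x.size, n + (window - half))
        out[n] = x[lo:hi].mean()
    return out


class TestLogGrid:
    def test_default_grid_endpoints(self):
        t = ll.log_grid_times(42, 50.0)
        assert t.size == 42
        assert t[0] == pytest.approx(0.0, abs=1e-12)
        assert t[-1] == pytest.approx(49.0)

    def test_two_point_grid(self):
        t = ll.log_grid_times(2, 10.0)
        assert t[0] == pytest.approx(0.0, abs=1e-12)
        assert t[1] == pytest.approx(9.0)

    def test_sample_conversion(self, cfg):
        # 0.5 ms at 30 kHz is 15 samples
        grid = ll.build_log_grid(cfg, 30000.0, n_s=0, n_e=10 ** 9)
        t = ll.log_grid_times(cfg.grid_points, cfg.grid_span_ms)
        j = int(np.argmin(np.abs(t - 0.5)))
        expected = int(round(t[j] * 1e-3 * 30000.0))
        # the node may have been merged; it must appear in the grid
        assert expected in grid.nodes

    def test_spacing_nondecreasing(self, cfg):
        """Log spacing means consecutive gaps never shrink: exactly in
        grid time, and up to rounding jitter in samples."""
        t = ll.log_grid_times(cfg.grid_points, cfg.grid_span_ms)
        assert np.all(np.diff(np.diff(t)) > 0)
        grid = ll.build_log_grid(cfg, 30000.0, n_s=30, n_e=10 ** 9)
        gaps = np.diff(grid.nodes)
        assert np.all(np.diff(gaps) >= -1)

    def test_duplicates_merged_at_low_fs(self, cfg):
        grid = ll.build_log_grid(cfg, 2000.0, n_s=0, n_e=10 ** 9)
        assert np.all(np.diff(grid.nodes) > 0)
        assert grid.n_points < cfg.grid_points

    def test_truncation_at_transient_end(self, cfg):
        grid = ll.build_log_grid(cfg, 30000.0, n_s=30, n_e=100)
        assert np.all(grid.nodes >= 30) and np.all(grid.nodes < 100)

    def test_empty_grid_beyond_end(self, cfg):
        grid = ll.build_log_grid(cfg, 30000.0, n_s=200, n_e=100)
        assert grid.n_points == 0


class TestNeighborhoodMean:
    def test_constant_trial(self):
        assert ll.neighborhood_mean(np.full(100, 7.5), 50, 8) == 7.5

    def test_eps_zero_is_single_sample(self):
        x = np.arange(100, dtype=float)
        assert ll.neighborhood_mean(x, 42, 0) == 42.0

    def test_linear_ramp_oracle(self):
        # brute-force mean of samples {8..12} of s(n) = n is 10
        x = np.arange(100, dtype=float)
        assert ll.neighborhood_mean(x, 10, 4) == np.mean(x[8:13]) == 10.0

    def test_empty_neighborhood_rejected(self):
        with pytest.raises(ValueError):
            ll.neighborhood_mean(np.zeros(10), 5, 0, lo=6, hi=6)


class TestTransientDetection:
    def test_same_statistics_no_transient(self, cfg, fs, rng):
        pre = rng.normal(0, 4, 200)
        trial = rng.normal(0, 4, int(0.05 * fs))
        assert not ll.detect_transient(trial, pre, cfg, fs)

    def test_decaying_step_detected(self, cfg, fs, rng):
        pre = rng.normal(0, 4, 200)
        trial = rng.normal(0, 4, int(0.05 * fs))
        t = np.arange(trial.size) / fs * 1e3
        trial = trial + 200.0 * np.exp(-t / 20.0)
        assert ll.detect_transient(trial, pre, cfg, fs)

    def test_short_trial_is_conservative(self, cfg, fs, rng):
        trial = rng.normal(0, 4, int(0.003 * fs))  # 3 ms
        assert ll.detect_transient(trial, rng.normal(0, 4, 100), cfg, fs)


class TestTransientEnd:
    def test_exponential_decay_matches_bruteforce(self, cfg, fs):
        """n_e of a decaying exponential equals a direct scan with an
        independently coded moving average."""
        n = int(0.1 * fs)
        t = np.arange(n) / fs * 1e3
        trial = 500.0 * np.exp(-t / 2.0)
        n_e = ll.find_transient_end(trial, cfg, fs)
        ma = brute_moving_average(
            trial, ms_to_samples(cfg.transient_window_ms, fs))
        med = np.median(trial[ms_to_samples(cfg.settling_ms, fs):])
        expected = int(np.nonzero(np.abs(ma - med)
                                  < cfg.steady_tol_uv)[0][0])
        assert n_e == expected

    def test_trial_shorter_than_settling(self, cfg, fs):
        trial = np.ones(int(0.03 * fs)) * 100  # 30 ms < 40 ms settling
        assert ll.find_transient_end(trial, cfg, fs) == trial.size

    def test_constant_trial_immediate(self, cfg, fs):
        trial = np.full(int(0.1 * fs), 3.0)
        assert ll.find_transient_end(trial, cfg, fs) == 0


class TestRecoveryStart:
    def test_no_saturation_default_blanking(self, cfg, fs):
        trial = np.random.default_rng(0).normal(0, 4, int(0.1 * fs))
        n_s, beta, sat = ll.find_recovery_start(trial, cfg, fs,
                                                -4750.0, 4750.0)
        assert n_s == ms_to_samples(1.0, fs)
        assert beta == pytest.approx(1.0)
        assert not sat

    def test_plateau_extends_blanking(self, cfg, fs):
        trial = np.zeros(int(0.1 * fs))
        p = ms_to_samples(3.0, fs)
        trial[:p] = 5000.0
        n_s, beta, sat = ll.find_recovery_start(trial, cfg, fs,
                                                -4750.0, 4750.0)
        assert n_s == p and sat
        assert beta == pytest.approx(3.0)

    def test_multiple_stretches_concatenated(self, cfg, fs):
        trial = np.zeros(int(0.1 * fs))
        trial[:ms_to_samples(1.5, fs)] = 5000.0
        a, b = ms_to_samples(2.0, fs), ms_to_samples(2.5, fs)
        trial[a:b] = -5000.0
        n_s, beta, sat = ll.find_recovery_start(trial, cfg, fs,
                                                -4750.0, 4750.0)
        assert n_s == b and sat

    def test_whole_trial_saturated(self, cfg, fs):
        trial = np.full(200, 5000.0)
        n_s, beta, sat = ll.find_recovery_start(trial, cfg, fs,
                                                -4750.0, 4750.0)
        assert n_s == 200 and sat

    def test_threshold_from_channel_max_when_limits_unknown(self, cfg):
        rec = ll.Recording(np.array([0.0, -1000.0, 500.0]), 1000.0)
        lo, hi = saturation_thresholds(rec, cfg)
        assert hi == pytest.approx(950.0) and lo == pytest.approx(-950.0)


class TestEstimateAndBridge:
    def test_exact_interpolant_zero_residual(self, fs):
        """A trial that is piecewise linear over the grid nodes (eps = 0)
        is reproduced exactly: residual 0 on [n_s, n_e)."""
        cfg = ll.LogLiraConfig(epsilon_cap=0.0)
        n_s, n_e = ms_to_samples(1.0, fs), int(0.04 * fs)
        grid = ll.build_log_grid(cfg, fs, n_s, n_e)
        rng = np.random.default_rng(5)
        node_vals = rng.normal(0, 100, grid.n_points)
        trial = np.interp(np.arange(int(0.05 * fs)),
                          np.concatenate([grid.nodes, [n_e]]),
                          np.concatenate([node_vals, [node_vals[-1]]]))
        art = ll.estimate_artifact(trial, grid, n_s, n_e)
        np.testing.assert_allclose(art[n_s:n_e], trial[n_s:n_e],
                                   atol=1e-9)

    def test_constant_trial_zero_residual(self, cfg, fs):
        n_s, n_e = ms_to_samples(1.0, fs), int(0.04 * fs)
        grid = ll.build_log_grid(cfg, fs, n_s, n_e)
        trial = np.full(int(0.05 * fs), 42.0)
        art = ll.estimate_artifact(trial, grid, n_s, n_e)
        np.testing.assert_allclose(art[n_s:n_e], 42.0)

    def test_blanked_region_pasted_unmodified(self, cfg, fs, rng):
        n_s, n_e = ms_to_samples(1.0, fs), int(0.04 * fs)
        grid = ll.build_log_grid(cfg, fs, n_s, n_e)
        trial = rng.normal(0, 10, int(0.05 * fs))
        art = ll.estimate_artifact(trial, grid, n_s, n_e)
        assert np.array_equal(art[:n_s], trial[:n_s])
        assert np.all(art[n_e:] == 0.0)

    def test_spike_survives_subtraction(self, cfg, fs):
        """A 1 ms biphasic spike riding on a smooth artifact keeps most of
        its amplitude after artifact subtraction."""
        n = int(0.06 * fs)
        t = np.arange(n) / fs * 1e3
        artifact = 800.0 * np.exp(-t / 4.0)
        spike = ll.spike_waveform_bank(fs)[0] * 80.0
        pos = int(0.02 * fs)  # 20 ms latency: grid is sparse here
        trial = artifact.copy()
        trial[pos:pos + spike.size] += spike
        n_s, n_e = ms_to_samples(1.0, fs), ll.find_transient_end(
            trial, cfg, fs)
        grid = ll.build_log_grid(cfg, fs, n_s, n_e)
        est = ll.estimate_artifact(trial, grid, n_s, n_e)
        resid = trial - est
        peak = np.abs(resid[pos:pos + spike.size]).max()
        assert peak == pytest.approx(80.0, rel=0.35)

    def test_zero_trial_bridges_to_zero(self, cfg, fs):
        trial = np.zeros(1000)
        out = ll.subtract_and_bridge(trial, np.zeros(1000), 20, 500, 0.0)
        np.testing.assert_allclose(out, 0.0)

    def test_bridge_is_two_point_line(self):
        trial = np.zeros(101)
        trial[100] = -10.0
        art = np.zeros(101)
        out = ll.subtract_and_bridge(trial, art, 100, 100, 10.0)
        # blanked region replaced by the line from +10 to -10
        expected = 10.0 + (-10.0 - 10.0) * (np.arange(100) + 1) / 101
        np.testing.assert_allclose(out[:100], expected)

    def test_output_continuous_at_recovery_boundaries(self, cfg, fs, rng):
        """Subtracting the estimate and bridging leaves no step at n_s or
        n_e: first differences there stay at the noise scale even though
        the raw artifact is hundreds of µV."""
        n = int(0.1 * fs)
        t = np.arange(n) / fs * 1e3
        noise_std = 2.0
        trial = 500.0 * np.exp(-t / 3.0) + rng.normal(0, noise_std, n)
        n_s = ms_to_samples(1.0, fs)
        n_e = ll.find_transient_end(trial, cfg, fs, start=n_s)
        grid = ll.build_log_grid(cfg, fs, n_s, n_e)
        art = ll.estimate_artifact(trial, grid, n_s, n_e)
        out = ll.subtract_and_bridge(trial, art, n_s, n_e, 0.0)
        for edge in (n_s, n_e):
            jump = np.abs(np.diff(out[edge - 5:edge + 5])).max()
            assert jump < 6 * noise_std

    def test_blank_only_touches_prefix(self, rng):
        trial = rng.normal(0, 3, 500)
        out = blank_only(trial, 30, 1.0)
        assert np.array_equal(out[30:], trial[30:])
        assert not np.array_equal(out[:30], trial[:30])


class TestCleanChannel:
    def test_noise_only_modified_within_beta0(self, noise_recording, cfg):
        """Idempotence on artifact-free signal: only the default blanking
        windows change."""
        rec, stims = noise_recording
        clean, fits = ll.clean_channel(rec, stims, cfg)
        b0 = ms_to_samples(1.0, rec.fs)
        mask = np.ones(rec.n_samples, bool)
        for o in stims.onsets:
            mask[o:o + b0] = False
        assert np.array_equal(clean.samples[mask], rec.samples[mask])
        assert not any(f.transient for f in fits)

    def test_prefix_untouched(self, noise_recording, cfg):
        rec, stims = noise_recording
        clean, _ = ll.clean_channel(rec, stims, cfg)
        first = int(stims.onsets[0])
        assert np.array_equal(clean.samples[:first], rec.samples[:first])

    def test_single_trial_skips_secondary(self, cfg, fs, rng):
        """With K < theta the secondary stage is the identity, so one
        synthetic artifact trial is exactly the stage-1 output."""
        n = int(0.3 * fs)
        sig = rng.normal(0, 4, n)
        t = np.arange(n - 2000) / fs * 1e3
        sig[2000:] += 900.0 * np.exp(-t / 5.0)
        rec = ll.Recording(sig, fs)
        stims = ll.StimTrain([2000])
        with_sec, _ = ll.clean_channel(rec, stims, cfg)
        without, _ = ll.clean_channel(rec, stims, cfg,
                                      run_secondary=False)
        assert np.array_equal(with_sec.samples, without.samples)

    def test_no_stimuli_identity(self, cfg, fs, rng):
        rec = ll.Recording(rng.normal(0, 4, 1000), fs)
        clean, fits = ll.clean_channel(rec, ll.StimTrain([]), cfg)
        assert np.array_equal(clean.samples, rec.samples)
        assert fits == []

    def test_output_length_preserved(self, noise_recording, cfg):
        rec, stims = noise_recording
        clean, _ = ll.clean_channel(rec, stims, cfg)
        assert clean.n_samples == rec.n_samples

    def test_fit_metadata_export(self, noise_recording, cfg):
        rec, stims = noise_recording
        _, fits = ll.clean_channel(rec, stims, cfg)
        df = ll.fits_to_dataframe(fits, stims)
        assert list(df.columns) == ["trial", "onset", "beta_ms", "n_s",
                                    "n_e", "transient", "saturated"]
        assert len(df) == stims.K
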