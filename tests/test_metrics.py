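"""Evaluation metrics: filtering, detection, RMSE, matching, C0, PSTH."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import loglira as ll
from loglira.synthetic import band_limited_noise, spike_waveform_bank


class TestBandpass:
    def test_dc_removed(self, fs):
        out = ll.bandpass(np.full(4000, 100.0), fs)
        assert np.abs(out[1000:-1000]).max() < 0.1  # > 60 dB down

    def test_in_band_tone_preserved(self, fs):
        t = np.arange(int(fs)) / fs
        out = ll.bandpass(np.sin(2 * np.pi * 1000 * t), fs)
        assert np.abs(out[2000:-2000]).max() == pytest.approx(1.0,
                                                              abs=0.05)

    def test_zero_phase_impulse_symmetric(self, fs):
        x = np.zeros(4001)
        x[2000] = 1.0
        out = ll.bandpass(x, fs)
        np.testing.assert_allclose(out[2000 - 500:2000],
                                   out[2000 + 500:2000:-1], atol=1e-10)

    def test_low_fs_reduces_cutoff_with_warning(self):
        with pytest.warns(UserWarning, match="cutoff"):
            out = ll.bandpass(np.random.default_rng(0).normal(size=4000),
                              10_000.0)
        assert out.size == 4000


class TestSWTTEO:
    def test_zero_signal_no_detections(self, fs):
        assert ll.detect_spikes_swtteo(np.zeros(5000), fs).size == 0

    def test_high_snr_spikes_found(self):
        """10 inserted 80 µV spikes in 4 µV noise are all recovered within
        ±0.2 ms."""
        fs = 30_000.0
        rng = np.random.default_rng(3)
        n = int(2.0 * fs)
        noise = band_limited_noise(n, fs, 4.0, rng)
        bank = spike_waveform_bank(fs)
        w = bank[0] * 80.0
        trough = int(np.argmin(bank[0]))
        times = (np.arange(10) + 1) * int(0.18 * fs)
        sig = noise.copy()
        for t in times:
            sig[t - trough:t - trough + w.size] += w
        det = ll.detect_spikes_swtteo(ll.bandpass(sig, fs), fs)
        m = ll.match_spikes(times, det, fs, jitter_ms=0.2)
        assert m.matched == 10 and m.fp == 0 and m.fn == 0

    def test_deterministic(self, fs, rng):
        x = ll.bandpass(rng.normal(0, 4, int(fs)), fs)
        a = ll.detect_spikes_swtteo(x, fs)
        b = ll.detect_spikes_swtteo(x, fs)
        assert np.array_equal(a, b)


class TestRMSE:
    def test_identical_signals(self, rng):
        x = rng.normal(size=100)
        assert ll.rmse(x, x) == 0.0

    def test_constant_offset(self, rng):
        x = rng.normal(size=100)
        assert ll.rmse(x, x + 5.0) == pytest.approx(5.0)

    def test_pythagorean_example(self):
        assert ll.rmse(np.zeros(2), np.array([3.0, 4.0])) == \
            pytest.approx(np.sqrt(25 / 2))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ll.rmse(np.zeros(3), np.zeros(4))

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_bruteforce_oracle_and_metric_axioms(self, seed):
        r = np.random.default_rng(seed)
        x, y, z = r.normal(0, 10, (3, 50))
        brute = np.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)) / 50)
        assert ll.rmse(x, y) == pytest.approx(brute)
        assert ll.rmse(x, y) == pytest.approx(ll.rmse(y, x))
        assert ll.rmse(x, z) <= ll.rmse(x, y) + ll.rmse(y, z) + 1e-12


class TestMatchSpikes:
    def test_identical_trains(self, fs):
        t = np.array([100, 2000, 30000])
        m = ll.match_spikes(t, t, fs)
        assert m.fp == 0 and m.fn == 0

    def test_small_shift_within_jitter(self, fs):
        t = np.array([1000, 5000, 9000])
        shift = int(round(0.1e-3 * fs))
        m = ll.match_spikes(t, t + shift, fs, jitter_ms=0.2)
        assert m.fp == 0 and m.fn == 0

    def test_large_shift_outside_jitter(self, fs):
        t = np.array([5000])
        shift = int(round(0.5e-3 * fs))
        m = ll.match_spikes(t, t + shift, fs, jitter_ms=0.2)
        assert m.fp == 1 and m.fn == 1

    def test_empty_ground_truth_flagged(self, fs):
        m = ll.match_spikes(np.array([]), np.array([100]), fs)
        assert m.gt_empty and m.fp == 1 and np.isnan(m.fp_pct)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_conservation(self, seed):
        """matched + FP = |det| and matched + FN = |gt|."""
        r = np.random.default_rng(seed)
        gt = np.unique(r.integers(0, 50000, 30))
        det = np.unique(r.integers(0, 50000, 30))
        m = ll.match_spikes(gt, det, 20000.0)
        assert m.matched + m.fp == det.size
        assert m.matched + m.fn == gt.size


class TestC0:
    def test_identity_is_one(self, fs, rng):
        x = np.sort(rng.choice(10 ** 6, 100, replace=False))
        assert ll.c0(x, x, fs) == 1.0

    def test_disjoint_is_zero(self, fs):
        x = np.array([0, 100000, 200000])
        assert ll.c0(x, x + 50000, fs) == 0.0

    def test_partial_coincidence(self, fs):
        # N_x = 4, N_y = 1, one coincidence -> 1/sqrt(4) = 0.5
        x = np.array([0, 100000, 200000, 300000])
        y = np.array([0])
        assert ll.c0(x, y, fs) == pytest.approx(0.5)

    def test_symmetry(self, fs, rng):
        x = np.sort(rng.choice(10 ** 6, 50, replace=False))
        y = np.sort(rng.choice(10 ** 6, 70, replace=False))
        assert ll.c0(x, y, fs) == pytest.approx(ll.c0(y, x, fs))

    def test_empty_train_zero(self, fs):
        assert ll.c0(np.array([]), np.array([1, 2]), fs) == 0.0

    def test_tolerance_window_width(self):
        """At 50 kHz the largest shift still scoring 1 is 0.2 ms: the
        total coincidence window is 0.4 ms wide."""
        fs = 50_000.0
        x = np.arange(10) * 50000
        max_shift = 0
        for shift in range(1, 30):
            if ll.c0(x, x + shift, fs) == 1.0:
                max_shift = shift
        assert 2 * max_shift / fs * 1e3 == pytest.approx(0.4)


class TestPSTH:
    def test_no_spikes_all_zero(self):
        edges, counts = ll.psth([np.array([])] * 10)
        assert counts.sum() == 0

    def test_single_bin_accumulates(self):
        lat = [np.array([1.1])] * 100
        edges, counts = ll.psth(lat, bin_ms=0.25, window_ms=10.0)
        k = int(np.digitize(1.1, edges)) - 1
        assert counts[k] == 100 and counts.sum() == 100
        assert edges[k] == pytest.approx(1.0)

    def test_count_conserved(self, rng):
        lat = [rng.uniform(0, 10, 5) for _ in range(20)]
        _, counts = ll.psth(lat, window_ms=10.0)
        assert counts.sum() == 100

    def test_align_truncates_stimuli(self, fs):
        spikes = np.array([100, 300, 500])
        onsets = np.array([0, 200, 400])
        lat = ll.align_to_onsets(spikes, onsets, fs, window_ms=10.0,
                                 max_stimuli=2)
        assert len(lat) == 2


class TestRunBenchmark:
    def test_identity_on_artifact_free_snippet_is_perfect(self, fs,
                                                          tmp_path):
        """Identity suppression of a snippet with no artifacts recovers
        the ground truth exactly: RMSE 0, FP = FN = 0, C0 = 1."""
        from loglira import io as lio
        basal = ll.gen_basal(ll.BasalSpec(duration=5.0, fs=fs,
                                          mfr_target=15.0, seed=1))
        rec = ll.Recording(basal.signal, fs)
        onsets = np.arange(5) * int(fs) + 1000
        lio.write_recording(tmp_path / "s.f32", rec)
        lio.write_recording(tmp_path / "s_basal.f32", rec)
        lio.write_event_train(tmp_path / "s_onsets.txt", onsets, fs)
        manifest = {"snippets": [{
            "id": "s", "mfr": 15, "mar": 1, "signal": "s.f32",
            "basal": "s_basal.f32", "onsets": "s_onsets.txt",
            "detection_params": ll.SWTTEOParams().to_dict()}]}
        rep = ll.run_benchmark(manifest, [ll.Suppressor()], tmp_path)
        row = rep.iloc[0]
        assert row.rmse_uv == pytest.approx(0.0, abs=1e-9)
        assert row.fp_pct == 0.0 and row.fn_pct == 0.0
        assert row.c0 == 1.0

    def test_identity_worse_than_loglira_with_artifacts(
            self, fs, small_dictionary, tmp_path):
        man = ll.build_benchmark([small_dictionary], tmp_path,
                                 mfr_values=[15], mar_values=[10],
                                 duration=5.0, fs=fs, seed=3)
        rep = ll.run_benchmark(
            man, [ll.Suppressor(), ll.LogLira(ll.LogLiraConfig(seed=0))],
            tmp_path)
        piv = rep.set_index("suppressor")
        assert piv.loc["identity", "rmse_uv"] > \
            piv.loc["loglira", "rmse_uv"]

    def test_row_count(self, fs, small_dictionary, tmp_path):
        man = ll.build_benchmark([small_dictionary], tmp_path,
                                 mfr_values=[10], mar_values=[6, 12],
                                 duration=5.0, fs=fs, seed=4)
        rep = ll.run_benchmark(man, [ll.Suppressor(),
                                     ll.DynamicAveraging()], tmp_path)
        assert len(rep) == 4
        summary = ll.summarize_benchmark(rep)
        assert summary.shape[0] == 2
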