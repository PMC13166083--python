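"""Synthetic stand-ins for real extracellular recordings.

Real study data is embargoed, so every downstream stage is exercised on
synthetic material: basal (stimulation-free) extracellular activity with a
known spike train at a target mean firing rate, parametric stimulation
artifact templates with fast transients, bi-exponential decays and optional
saturation plateaus, and stimulus onset trains whose inter-artifact
intervals follow a heavy-tailed distribution with a prescribed mean
artifact rate MAR = 1/median(IAI).

Defaults: background noise is Gaussian, band-limited to 300-6000 Hz, 4 µV
standard deviation; spike peak amplitudes are uniform over 30-120 µV;
inter-spike intervals are gamma-distributed (shape 2) with a 2 ms
refractory period — plausible cortical extracellular scales in which only
the amplitude ratios matter for the tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sps

from .config import ms_to_samples
from .core import StimTrain

MFR_VALUES = (5, 10, 15, 20, 25)
MAR_VALUES = (2, 4, 6, 8, 10, 12, 14, 16, 18, 20)
MFR_TOL_HZ = 0.5
MAR_TOL_HZ = 0.1


@dataclass
class BasalSpec:
    """Parameters of a synthetic basal-activity segment."""

    duration: float = 150.0          # s
    fs: float = 30_000.0             # Hz
    mfr_target: float = 10.0         # Hz
    mfr_tol: float = MFR_TOL_HZ      # Hz
    noise_std: float = 4.0           # µV
    spike_amplitude_range: tuple[float, float] = (30.0, 120.0)  # µV
    refractory_ms: float = 2.0
    isi_shape: float = 2.0           # gamma ISI shape
    seed: int = 0


@dataclass
class SyntheticTemplateSpec:
    """Parameters of a parametric artifact-template family."""

    n_templates: int = 8
    duration_ms: float = 50.0
    tau_fast_ms: float = 0.3
    tau_slow_ms: float = 8.0
    peak_uv: float = 4000.0          # transient peak magnitude
    decay_uv: float = 300.0          # slow-decay initial magnitude
    saturation: bool = False
    plateau_ms: float = 2.0
    jitter: float = 0.15             # relative per-template perturbation
    seed: int = 0


@dataclass
class GroundTruth:
    """A basal segment with exact spike bookkeeping.

    ``signal = noise + spike_track`` holds bit-exactly by construction.
    """

    signal: np.ndarray
    noise: np.ndarray
    spike_track: np.ndarray
    spike_times: np.ndarray          # samples, aligned to waveform trough
    waveform_ids: np.ndarray
    fs: float
    mfr_realized: float


def spike_waveform_bank(fs: float) -> list[np.ndarray]:
    """Three canonical ~1 ms extracellular waveforms, trough-normalized.

    Two biphasic shapes (narrow and broad) and one triphasic shape, each
    scaled so its trough is exactly -1.
    """
    t = np.arange(int(round(1.6e-3 * fs))) / fs * 1e3  # ms
    shapes = []
    for pre, trough_w, reb_w, reb_a in [(0.0, 0.10, 0.25, 0.35),
                                        (0.0, 0.16, 0.35, 0.45),
                                        (0.25, 0.12, 0.28, 0.40)]:
        w = -np.exp(-0.5 * ((t - 0.55) / trough_w) ** 2)
        w += reb_a * np.exp(-0.5 * ((t - 0.95) / reb_w) ** 2)
        if pre:
            w += pre * np.exp(-0.5 * ((t - 0.25) / 0.09) ** 2)
        shapes.append(w / abs(w.min()))
    return shapes


def band_limited_noise(n: int, fs: float, std: float,
                       rng: np.random.Generator,
                       band: tuple[float, float] = (300.0, 6000.0)
                       ) -> np.ndarray:
    """Gaussian noise band-limited to ``band`` and rescaled to ``std``."""
    x = rng.standard_normal(n)
    if std == 0 or n < 50:
        return np.zeros(n) if std == 0 else x * std
    hi = min(band[1], 0.45 * fs)
    sos = sps.butter(4, [band[0], hi], btype="bandpass", fs=fs,
                     output="sos")
    x = sps.sosfiltfilt(sos, x)
    s = x.std()
    return x * (std / s) if s > 0 else x


def _draw_spike_times(spec: BasalSpec, rng: np.random.Generator
                      ) -> np.ndarray:
    """Gamma-ISI spike times (seconds) with refractory enforcement."""
    rate = spec.mfr_target
    refr = spec.refractory_ms * 1e-3
    if rate <= 0:
        return np.array([])
    if 1.0 / rate <= refr:
        raise ValueError(f"MFR {rate} Hz unreachable with "
                         f"{spec.refractory_ms} ms refractory period")
    n_draw = int(rate * spec.duration * 2) + 20
    # refractory inflates the mean ISI; compensate in the gamma scale
    scale = (1.0 / rate - refr * 0.12) / spec.isi_shape
    isi = rng.gamma(spec.isi_shape, max(scale, 1e-6), size=n_draw)
    isi = np.maximum(isi, refr)
    times = np.cumsum(isi)
    return times[times < spec.duration - 2e-3]


def gen_basal(spec: BasalSpec) -> GroundTruth:
    """Generate a basal segment: band-limited noise + inserted spikes.

    The realized mean firing rate (spike count / duration) is within
    ``mfr_tol`` of the target; the draw is repeated if a realization falls
    outside the tolerance. Fully deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    bank = spike_waveform_bank(spec.fs)
    troughs = [int(np.argmin(w)) for w in bank]

    times_s = np.array([])
    if spec.mfr_target > 0:
        for _ in range(100):
            times_s = _draw_spike_times(spec, rng)
            rate = times_s.size / spec.duration
            if abs(rate - spec.mfr_target) <= spec.mfr_tol:
                break
        else:
            raise RuntimeError("could not realize the target MFR within "
                               "tolerance")

    noise = band_limited_noise(n, spec.fs, spec.noise_std, rng)
    track = np.zeros(n)
    ids = rng.integers(0, len(bank), size=times_s.size)
    amps = rng.uniform(*spec.spike_amplitude_range, size=times_s.size)
    spike_samples = np.round(times_s * spec.fs).astype(np.int64)
    kept, kept_ids = [], []
    for t, wid, a in zip(spike_samples, ids, amps):
        w = bank[wid] * a
        start = int(t) - troughs[wid]
        if start < 0 or start + w.size > n:
            continue
        track[start:start + w.size] += w
        kept.append(int(t))
        kept_ids.append(int(wid))
    return GroundTruth(signal=noise + track, noise=noise, spike_track=track,
                       spike_times=np.asarray(kept, dtype=np.int64),
                       waveform_ids=np.asarray(kept_ids, dtype=np.int64),
                       fs=spec.fs,
                       mfr_realized=len(kept) / spec.duration)


def gen_templates(spec: SyntheticTemplateSpec, fs: float,
                  amp_limits: Optional[tuple[float, float]] = None
                  ) -> np.ndarray:
    """Parametric artifact templates: biphasic transient + bi-exponential
    decay, optionally clipped to the amplifier limits with an exact
    saturation plateau. Returns an (n_templates, L) array."""
    if spec.saturation and amp_limits is None:
        raise ValueError("saturated templates require amp_limits")
    L = ms_to_samples(spec.duration_ms, fs)
    plateau = ms_to_samples(spec.plateau_ms, fs)
    if spec.saturation and plateau >= L:
        raise ValueError("saturation plateau must be shorter than the "
                         "template")
    rng = np.random.default_rng(spec.seed)
    t = np.arange(L) / fs * 1e3  # ms
    out = np.empty((spec.n_templates, L))
    for i in range(spec.n_templates):
        j = 1.0 + spec.jitter * rng.uniform(-1, 1, size=4)
        sign = rng.choice([-1.0, 1.0])
        tau_f = spec.tau_fast_ms * j[0]
        tau_s = spec.tau_slow_ms * j[1]
        # biphasic transient: sharp positive lobe then negative rebound
        w = sign * spec.peak_uv * j[2] * (
            np.exp(-t / tau_f) - 0.6 * np.exp(-t / (2.5 * tau_f)))
        # cap the slow component so every template decays below 1 µV
        # before the end of its span
        a_s = spec.decay_uv * j[3]
        tail = a_s * np.exp(-t[-1] / tau_s)
        if tail > 0.5:
            a_s *= 0.5 / tail
        w += -sign * a_s * np.exp(-t / tau_s)
        if spec.saturation:
            lo, hi = amp_limits
            limit = hi if sign > 0 else lo
            w[:plateau] = limit
            w = np.clip(w, lo, hi)
        out[i] = w
    return out


def gen_stim_onsets(mar_target: float, duration: float, fs: float,
                    seed: int = 0, constant: bool = False,
                    sigma: float = 0.6, start_s: float = 0.1,
                    tol: float = MAR_TOL_HZ) -> StimTrain:
    """Stimulus onset train with heavy-tailed (log-normal) IAIs.

    The drawn IAIs are rescaled so that 1/median(IAI) hits the target MAR
    exactly before truncation at ``duration``; the realized value is
    verified to stay within ``tol``. ``constant=True`` yields a degenerate
    evenly spaced train.
    """
    if mar_target <= 0:
        raise ValueError("MAR target must be positive")
    if duration * mar_target < 2:
        raise ValueError("duration too short to place two onsets")
    if constant:
        step = 1.0 / mar_target
        times = np.arange(start_s, duration, step)
        return StimTrain(np.round(times * fs).astype(np.int64))
    rng = np.random.default_rng(seed)
    for _ in range(50):
        n_draw = int(duration * mar_target * 2) + 10
        iai = rng.lognormal(mean=0.0, sigma=sigma, size=n_draw)
        iai *= (1.0 / mar_target) / np.median(iai)
        times = start_s + np.concatenate(([0.0], np.cumsum(iai)))
        times = times[times < duration]
        if times.size < 2:
            continue
        realized = 1.0 / np.median(np.diff(times))
        if abs(realized - mar_target) <= tol:
            onsets = np.round(times * fs).astype(np.int64)
            return StimTrain(np.unique(onsets))
    raise RuntimeError("could not realize the target MAR within tolerance")


def insert_evoked_spikes(gt: GroundTruth, stims: StimTrain,
                         latency_range_ms: tuple[float, float] = (1.0, 5.0),
                         jitter_ms: float = 0.3, prob: float = 0.8,
                         amplitude_uv: float = 80.0, seed: int = 0
                         ) -> GroundTruth:
    """Evoked mode: add spikes time-locked to stimulus onsets.

    Each stimulus elicits a spike with probability ``prob`` at a per-trial
    latency drawn uniformly from ``latency_range_ms`` plus Gaussian jitter.
    Returns a new GroundTruth with the extra spikes merged in.
    """
    rng = np.random.default_rng(seed)
    bank = spike_waveform_bank(gt.fs)
    troughs = [int(np.argmin(w)) for w in bank]
    n = gt.signal.size
    track = gt.spike_track.copy()
    new_times, new_ids = list(gt.spike_times), list(gt.waveform_ids)
    for onset in stims.onsets:
        if rng.uniform() > prob:
            continue
        lat = rng.uniform(*latency_range_ms) + rng.normal(0, jitter_ms)
        t = int(onset) + ms_to_samples(max(lat, 0.5), gt.fs)
        wid = int(rng.integers(0, len(bank)))
        w = bank[wid] * amplitude_uv
        start = t - troughs[wid]
        if start < 0 or start + w.size > n:
            continue
        track[start:start + w.size] += w
        new_times.append(t)
        new_ids.append(wid)
    order = np.argsort(new_times)
    times = np.asarray(new_times, dtype=np.int64)[order]
    return GroundTruth(signal=gt.noise + track, noise=gt.noise,
                       spike_track=track, spike_times=times,
                       waveform_ids=np.asarray(new_ids,
                                               dtype=np.int64)[order],
                       fs=gt.fs,
                       mfr_realized=times.size / (n / gt.fs))
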