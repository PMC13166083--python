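"""Semisynthetic snippet synthesis.

The benchmark pipeline has three stages: build per-channel dictionaries of
artifact templates from a recording (cluster the per-stimulus waveforms,
median each accepted cluster, smooth), resample the channel's
inter-artifact intervals to a target mean artifact rate via kernel density
estimation, and assemble snippets by inserting windowed templates on top of
a basal ground-truth segment. Because the snippet is constructed as
``basal + artifact track``, the decomposition is exact and the ground-truth
spike train is untouched by template placement.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps
from scipy.stats import gaussian_kde

from . import io as lio
from .config import LogLiraConfig, ms_to_samples
from .core import Recording, StimTrain
from .secondary import cluster_density, embed_windows
from .synthetic import (BasalSpec, GroundTruth, MAR_TOL_HZ, MAR_VALUES,
                        MFR_VALUES, gen_basal)

MIN_DICTIONARY_CLUSTER = 100


class DictionaryError(ValueError):
    """No artifact cluster was large enough to yield a template."""


@dataclass
class TemplateDictionary:
    """Per-channel artifact templates plus the channel's onset train."""

    channel_id: str
    templates: np.ndarray            # (n_templates, L)
    source_onsets: np.ndarray        # samples
    fs: float

    @property
    def n_templates(self) -> int:
        return int(self.templates.shape[0])

    @property
    def template_length(self) -> int:
        return int(self.templates.shape[1])


@dataclass
class SnippetSpec:
    mfr_target: float
    mar_target: float
    duration: float = 150.0
    seed: int = 0


@dataclass
class Snippet:
    """A semisynthetic ground-truth segment."""

    signal: np.ndarray
    artifact_track: np.ndarray
    basal: GroundTruth
    onsets: np.ndarray
    template_ids: np.ndarray
    fs: float
    mfr_realized: float
    mar_realized: float


def _smooth_template(wave: np.ndarray, fs: float,
                     cutoff: float = 2000.0) -> np.ndarray:
    """Low-pass the median template with a minimum-order FIR filter
    (~2 kHz cutoff), applied forward-backward for zero phase."""
    width = min(500.0, 0.4 * cutoff)
    numtaps, beta = sps.kaiserord(60.0, width / (0.5 * fs))
    numtaps = max(numtaps | 1, 3)
    if wave.size <= 3 * numtaps:
        numtaps = max((wave.size // 3) | 1, 3)
    taps = sps.firwin(numtaps, cutoff, window=("kaiser", beta), fs=fs)
    return sps.filtfilt(taps, [1.0], wave,
                        padlen=min(3 * numtaps, wave.size - 1))


def _merge_saturated(median_t: np.ndarray, smoothed: np.ndarray
                     ) -> np.ndarray:
    """Preserve the raw median up to the last point where it departs from
    the smoothed version by more than 2.5x the median departure — keeps the
    onset transient and saturation clip edges sharp while the tail stays
    smooth."""
    d = np.abs(median_t - smoothed)
    m = float(np.median(d))
    if m <= 0:
        return smoothed
    above = np.nonzero(d > 2.5 * m)[0]
    if above.size == 0:
        return smoothed
    cut = int(above[-1])
    out = smoothed.copy()
    out[:cut + 1] = median_t[:cut + 1]
    return out


def build_dictionary(recording: Recording, stims: StimTrain,
                     cfg: Optional[LogLiraConfig] = None,
                     min_members: int = MIN_DICTIONARY_CLUSTER
                     ) -> TemplateDictionary:
    """Learn a channel's artifact-template dictionary.

    All per-stimulus waveforms (common length = the minimum IAI) are
    embedded to two dimensions and density-clustered; clusters with fewer
    than ``min_members`` members are discarded. Each accepted cluster
    yields one template: the per-sample median of its members, low-pass
    smoothed; for clusters containing saturation, the raw median is kept up
    to the last large median/smoothed discrepancy so the clip edges
    survive.
    """
    cfg = cfg or LogLiraConfig()
    fs = recording.fs
    if stims.K < min_members:
        raise DictionaryError(
            f"{stims.K} artifacts < {min_members} required")
    L = int(np.min(np.diff(stims.onsets)))
    keep = stims.onsets[stims.onsets + L <= recording.n_samples]
    waves = np.stack([recording.samples[o:o + L] for o in keep])
    if waves.shape[0] < min_members:
        raise DictionaryError("too few full-length artifact waveforms")

    embedding = embed_windows(waves, cfg)
    assignment = cluster_density(embedding, theta=min_members)
    if not assignment.retained:
        raise DictionaryError("no artifact cluster reached "
                              f"{min_members} members")

    if recording.amp_limits is not None:
        lo, hi = recording.amp_limits
        sat_lo, sat_hi = cfg.sat_fraction * lo, cfg.sat_fraction * hi
    else:
        peak = float(np.max(np.abs(recording.samples)))
        sat_lo, sat_hi = -cfg.sat_fraction * peak, cfg.sat_fraction * peak

    templates = []
    for cid in assignment.retained:
        members = waves[assignment.labels == cid]
        median_t = np.median(members, axis=0)
        smoothed = _smooth_template(median_t, fs)
        saturated = bool(np.any((members >= sat_hi) | (members <= sat_lo)))
        templates.append(_merge_saturated(median_t, smoothed)
                         if saturated else smoothed)
    return TemplateDictionary(channel_id=recording.channel_id,
                              templates=np.stack(templates),
                              source_onsets=stims.onsets.copy(), fs=fs)


def resample_iai(source_iai: np.ndarray, mar_target: float,
                 duration: float, seed: int = 0,
                 tol: float = MAR_TOL_HZ, trim_fraction: float = 0.02,
                 max_retries: int = 50) -> np.ndarray:
    """Resample inter-artifact intervals to a target MAR.

    The source IAIs are first adjusted: shifted rightward when the target
    MAR is below the source one (a constant shift placing the median at
    1/MAR), or trimmed of their largest values in small steps when it is
    above (the minimum IAI stays in place). A Gaussian KDE (Silverman
    bandwidth) of the adjusted IAIs is then sampled, truncated to their
    [min, max] range, accumulating intervals until the cumulative sum
    covers ``duration``; draws whose realized 1/median misses the target by
    more than ``tol`` are rejected and redrawn.
    """
    source_iai = np.asarray(source_iai, dtype=np.float64)
    if source_iai.size < 2:
        raise ValueError("need at least two source IAIs")
    if mar_target > 1.0 / source_iai.min():
        raise ValueError(f"target MAR {mar_target} Hz exceeds the "
                         "reciprocal of the minimum source IAI")
    adjusted = np.sort(source_iai)
    current = 1.0 / np.median(adjusted)
    if mar_target < current - tol:
        adjusted = adjusted + (1.0 / mar_target - np.median(adjusted))
    elif mar_target > current + tol:
        while 1.0 / np.median(adjusted) < mar_target - tol \
                and adjusted.size > 2:
            n_drop = max(int(np.floor(trim_fraction * adjusted.size)), 1)
            adjusted = adjusted[:-n_drop]
        if abs(1.0 / np.median(adjusted) - mar_target) > tol:
            # trim step overshot: recentre the median with a small shift
            adjusted = adjusted + (1.0 / mar_target - np.median(adjusted))
            adjusted = adjusted[adjusted > 0]

    lo, hi = float(adjusted.min()), float(adjusted.max())
    kde = gaussian_kde(adjusted, bw_method="silverman")
    rng = np.random.default_rng(seed)
    n_need = int(duration * mar_target * 2) + 10

    def _draw(total_needed: float) -> list[float]:
        draws: list[float] = []
        total = 0.0
        while total < total_needed:
            batch = kde.resample(n_need, seed=rng).ravel()
            batch = batch[(batch >= lo) & (batch <= hi)]
            if batch.size == 0:
                continue
            for v in batch:
                draws.append(float(v))
                total += v
                if total >= total_needed:
                    break
        return draws

    for _ in range(max_retries):
        iai = np.asarray(_draw(duration))
        if abs(1.0 / np.median(iai) - mar_target) <= tol:
            return iai
        # the sample median fluctuates more than the tolerance for short
        # snippets: recentre with a small constant shift (clipped back to
        # the support), then top the sequence back up to the duration
        for _ in range(5):
            iai = np.clip(iai + (1.0 / mar_target - np.median(iai)),
                          lo, hi)
            deficit = duration - float(np.sum(iai))
            if deficit > 0:
                iai = np.concatenate([iai, _draw(deficit)])
            if abs(1.0 / np.median(iai) - mar_target) <= tol \
                    and np.sum(iai) >= duration:
                return iai
    raise RuntimeError("could not realize the target MAR within tolerance")


def insertion_window(length: int, fs: float, alpha: float = 1.0,
                     ramp_ms: float = 0.2) -> np.ndarray:
    """Template insertion window: zero endpoints, fast onset.

    A short raised-cosine ramp preserves the artifact's fast onset
    transient while the decaying half of a Blackman window (raised to the
    per-insertion exponent ``alpha``, which modulates the decay speed)
    forces the tail to zero, so the inserted template joins the snippet
    without discontinuities at either end.
    """
    if length < 8:
        w = np.blackman(max(length, 1))
        if length:
            w[0], w[-1] = 0.0, 0.0
        return w
    ramp = min(max(ms_to_samples(ramp_ms, fs), 1), length // 4)
    w = np.empty(length)
    w[:ramp] = np.sin(0.5 * np.pi * np.arange(ramp) / ramp) ** 2
    d = length - ramp
    half = np.blackman(2 * d + 1)[d:2 * d]
    w[ramp:] = np.clip(half / half[0], 0.0, None) ** alpha
    w[-1] = 0.0
    return w


def synthesize_snippet(spec: SnippetSpec, dictionary: TemplateDictionary,
                       basal: GroundTruth) -> Snippet:
    """Assemble a snippet: windowed templates at resampled onsets + basal.

    Templates are drawn at random from the dictionary; one overlapping a
    following onset is truncated there before windowing. The ground-truth
    spike train is the basal one, by construction independent of artifact
    placement.
    """
    if dictionary.n_templates == 0:
        raise ValueError("empty template dictionary")
    fs = dictionary.fs
    if basal.fs != fs:
        raise ValueError("basal and dictionary sampling rates differ")
    n = int(round(spec.duration * fs))
    if basal.signal.size < n:
        raise ValueError("basal segment shorter than the snippet")
    rng = np.random.default_rng(spec.seed)
    source_iai = np.diff(dictionary.source_onsets) / fs
    # the onset train keeps the continuous draw's MAR only approximately
    # (truncation at the snippet end drops intervals), so verify the
    # realized rate on the final train and redraw when it drifts
    for _ in range(50):
        iai = resample_iai(source_iai, spec.mar_target, spec.duration,
                           seed=int(rng.integers(2 ** 31)))
        times = np.cumsum(iai)
        times = times[times < spec.duration - 1.0 / fs]
        onsets = np.unique(np.round(times * fs).astype(np.int64))
        if onsets.size < 2:
            continue
        realized = 1.0 / float(np.median(np.diff(onsets) / fs))
        if abs(realized - spec.mar_target) <= MAR_TOL_HZ:
            break
    else:
        raise RuntimeError("could not realize the target MAR on the "
                           "onset train within tolerance")

    track = np.zeros(n)
    ids = rng.integers(0, dictionary.n_templates, size=onsets.size)
    alphas = rng.uniform(0.5, 2.0, size=onsets.size)
    bounds = np.append(onsets, n)
    for k, onset in enumerate(onsets):
        avail = min(dictionary.template_length,
                    int(bounds[k + 1]) - int(onset))
        if avail <= 0:
            continue
        tpl = dictionary.templates[ids[k], :avail]
        track[onset:onset + avail] += tpl * insertion_window(
            avail, fs, alphas[k])

    signal = track + basal.signal[:n]
    mar_realized = 1.0 / np.median(np.diff(onsets) / fs) \
        if onsets.size > 1 else np.nan
    spike_times = basal.spike_times[basal.spike_times < n]
    return Snippet(signal=signal, artifact_track=track, basal=basal,
                   onsets=onsets, template_ids=ids, fs=fs,
                   mfr_realized=spike_times.size / spec.duration,
                   mar_realized=mar_realized)


def build_benchmark(dictionaries: Sequence[TemplateDictionary],
                    outdir: str | Path,
                    mfr_values: Sequence[float] = MFR_VALUES,
                    mar_values: Sequence[float] = MAR_VALUES,
                    duration: float = 150.0,
                    fs: Optional[float] = None,
                    noise_std: float = 4.0,
                    seed: int = 0,
                    detection_params: Optional[dict] = None) -> dict:
    """Generate one snippet per (MFR, MAR) cell per dictionary subset.

    Each dictionary plays the role of one subset's channel: a full default
    grid yields 5 x 10 = 50 snippets per subset. Signals, onset trains and
    ground-truth data are written under ``outdir`` with a JSON manifest
    recording specs, seeds and realized rates.
    """
    from .metrics import SWTTEOParams

    if not dictionaries:
        raise ValueError("at least one template dictionary is required")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    det = detection_params or SWTTEOParams().to_dict()
    entries = []
    rng = np.random.default_rng(seed)
    for d_idx, dictionary in enumerate(dictionaries):
        fs_d = fs or dictionary.fs
        for mfr in mfr_values:
            basal = gen_basal(BasalSpec(duration=duration, fs=fs_d,
                                        mfr_target=mfr,
                                        noise_std=noise_std,
                                        seed=int(rng.integers(2 ** 31))))
            for mar in mar_values:
                sid = f"s{d_idx}_mfr{mfr:g}_mar{mar:g}"
                snip_seed = int(rng.integers(2 ** 31))
                snippet = synthesize_snippet(
                    SnippetSpec(mfr_target=mfr, mar_target=mar,
                                duration=duration, seed=snip_seed),
                    dictionary, basal)
                _check_rates(sid, mfr, mar, snippet)
                lio.write_recording(outdir / f"{sid}.f32",
                                    Recording(snippet.signal, fs_d,
                                              channel_id=sid))
                lio.write_recording(outdir / f"{sid}_basal.f32",
                                    Recording(basal.signal[:snippet.signal.size],
                                              fs_d, channel_id=sid))
                lio.write_event_train(outdir / f"{sid}_onsets.txt",
                                      snippet.onsets, fs_d)
                lio.write_event_train(outdir / f"{sid}_spikes.txt",
                                      snippet.basal.spike_times, fs_d)
                entries.append({
                    "id": sid, "subset": d_idx, "mfr": mfr, "mar": mar,
                    "seed": snip_seed, "fs": fs_d, "duration": duration,
                    "mfr_realized": snippet.mfr_realized,
                    "mar_realized": snippet.mar_realized,
                    "n_stimuli": int(snippet.onsets.size),
                    "signal": f"{sid}.f32", "basal": f"{sid}_basal.f32",
                    "onsets": f"{sid}_onsets.txt",
                    "spikes": f"{sid}_spikes.txt",
                    "detection_params": det,
                })
    manifest = {"seed": seed, "duration": duration,
                "mfr_values": list(mfr_values),
                "mar_values": list(mar_values),
                "n_subsets": len(dictionaries),
                "snippets": entries}
    lio.write_manifest(outdir / "manifest.json", manifest)
    return manifest


def _check_rates(sid: str, mfr: float, mar: float,
                 snippet: Snippet) -> None:
    if abs(snippet.mar_realized - mar) > MAR_TOL_HZ:
        raise RuntimeError(f"{sid}: realized MAR {snippet.mar_realized:.3f}"
                           f" misses target {mar}")
    if abs(snippet.mfr_realized - mfr) > 0.5:
        raise RuntimeError(f"{sid}: realized MFR {snippet.mfr_realized:.3f}"
                           f" misses target {mfr}")
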