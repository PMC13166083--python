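"""Per-trial artifact estimation (stage 1).

Each stimulation artifact is handled individually. The stage proceeds as:

1. decide whether the trial carries a significant artifact transient at all
   (channels far from the stimulation site often do not);
2. if it does, locate the transient's end ``n_e`` by intersecting a 5 ms
   moving average with the trial's steady-state median;
3. locate the recovery start ``n_s``: the first sample after the default
   blanking period, pushed further right while the amplifier is saturated
   (the actual blanking period ``beta`` follows);
4. estimate the artifact by piecewise-linear interpolation between
   logarithmically spaced points — dense right after the pulse, where the
   artifact dynamics are fastest — each point's value being a local
   neighborhood mean of the signal;
5. subtract the estimate and bridge the blanked region with a line from the
   sample preceding the onset to the sample following ``n_e``, so the output
   has no step discontinuities that would ring after bandpass filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import LogLiraConfig, ms_to_samples
from .core import Recording, StimTrain, segment_trials


@dataclass
class LogGrid:
    """Logarithmic interpolation grid, already shifted into a trial.

    ``t_ms`` are the grid times before shifting; ``nodes`` are the retained
    sample indices (within the trial, after shifting by the blanking
    interval and truncation at ``n_e``, duplicates merged); ``eps`` is the
    neighborhood width schedule per retained node.
    """

    t_ms: np.ndarray
    nodes: np.ndarray
    eps: np.ndarray

    @property
    def n_points(self) -> int:
        return int(self.nodes.size)


@dataclass
class TrialArtifactFit:
    """Landmarks and artifact estimate for one trial."""

    beta_ms: float
    n_s: int
    n_e: int
    artifact: Optional[np.ndarray]
    transient: bool
    saturated: bool
    pre_window_overlap: bool = False


def log_grid_times(P: int, T: float) -> np.ndarray:
    """Grid times t_j = 10**(j/(P-1) * log10(T)) - 1 for j = 0..P-1 (ms).

    The endpoints are t_0 = 0 and t_{P-1} = T - 1 exactly; spacing grows
    with j, so points are densest immediately after the pulse.
    """
    if P < 2:
        raise ValueError("P must be >= 2")
    j = np.arange(P)
    return 10.0 ** (j / (P - 1) * np.log10(T)) - 1.0


def build_log_grid(cfg: LogLiraConfig, fs: float, n_s: int,
                   n_e: int) -> LogGrid:
    """Convert grid times to samples, shift by the blanking interval and
    truncate at the transient end.

    Duplicate sample indices (inevitable at low sampling rates, where the
    early log-spaced times round to the same sample) are merged.
    """
    t = log_grid_times(cfg.grid_points, cfg.grid_span_ms)
    n = np.round(t * 1e-3 * fs).astype(np.int64) + n_s
    n = np.unique(n[n < n_e])
    return LogGrid(t_ms=t, nodes=n, eps=_eps_schedule(n, cfg.epsilon_cap))


def _eps_schedule(nodes: np.ndarray, cap: float) -> np.ndarray:
    """Neighborhood width per node, roughly proportional to the local pitch.

    Interior nodes use half the span between their two neighbors, capped at
    ``cap`` times the forward spacing; endpoints use the one-sided spacing.
    """
    m = nodes.size
    eps = np.zeros(m, dtype=np.int64)
    if m < 2:
        return eps
    fwd = np.diff(nodes)
    for j in range(m):
        if j == 0:
            e, f = fwd[0], fwd[0]
        elif j == m - 1:
            e, f = fwd[-1], fwd[-1]
        else:
            e, f = (nodes[j + 1] - nodes[j - 1]) // 2, fwd[j]
        eps[j] = min(int(e), int(np.floor(cap * f)))
    return eps


def neighborhood_mean(trial: np.ndarray, n_j: int, eps: int,
                      lo: int = 0, hi: Optional[int] = None) -> float:
    """Mean of the eps+1 samples centered on ``n_j``, clipped to [lo, hi)."""
    if hi is None:
        hi = trial.size
    a = max(int(n_j) - eps // 2, lo)
    b = min(int(n_j) + (eps - eps // 2) + 1, hi)
    if b <= a:
        raise ValueError(f"empty neighborhood at node {n_j}")
    return float(np.mean(trial[a:b]))


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge truncation (shrinking window)."""
    window = max(int(window), 1)
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(x, dtype=np.float64)))
    idx = np.arange(x.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + (window - half), x.size)
    return (csum[hi] - csum[lo]) / (hi - lo)


def detect_transient(trial: np.ndarray, pre_window: np.ndarray,
                     cfg: LogLiraConfig, fs: float) -> bool:
    """Does this trial carry a significant artifact transient beyond the
    default blanking interval?

    Compares a window of ``transient_window_ms`` immediately preceding the
    stimulus onset with one immediately following the default blanking
    period. No transient is declared when the means differ by at most
    ``transient_mean_k`` pre-window standard deviations and the standard
    deviation ratio stays within ``transient_std_ratio``. Trials too short
    to hold the post-window (or with no pre-onset signal available) are
    conservatively treated as containing a transient.
    """
    w = ms_to_samples(cfg.transient_window_ms, fs)
    b0 = ms_to_samples(cfg.beta0_ms, fs)
    if trial.size < b0 + w or pre_window.size < 2:
        return True
    post = trial[b0:b0 + w]
    pre_std = float(np.std(pre_window))
    if pre_std == 0.0:
        # flat reference: any deviation is a transient
        return not np.allclose(post, pre_window[-1])
    mean_ok = abs(float(np.mean(post)) - float(np.mean(pre_window))) \
        <= cfg.transient_mean_k * pre_std
    ratio = float(np.std(post)) / pre_std
    lo, hi = cfg.transient_std_ratio
    return not (mean_ok and lo <= ratio <= hi)


def find_transient_end(trial: np.ndarray, cfg: LogLiraConfig, fs: float,
                       start: int = 0) -> int:
    """Locate the end of the artifact transient.

    A moving average of ``transient_window_ms`` is compared against the
    median steady-state value (computed over samples beyond the settling
    time); ``n_e`` is the first sample, at or after ``start``, where the
    filtered trial enters the ±``steady_tol_uv`` band around that median.
    If the whole trial is shorter than the settling time, or the band is
    never entered, ``n_e`` is the end of the trial.
    """
    N = trial.size
    settle = ms_to_samples(cfg.settling_ms, fs)
    if N <= settle:
        med = float(np.median(trial))
        short = True
    else:
        med = float(np.median(trial[settle:]))
        short = False
    ma = moving_average(trial, ms_to_samples(cfg.transient_window_ms, fs))
    inside = np.abs(ma - med) < cfg.steady_tol_uv
    hits = np.nonzero(inside[start:])[0]
    if short or hits.size == 0:
        return N
    return int(start + hits[0])


def saturation_thresholds(recording: Recording,
                          cfg: LogLiraConfig) -> tuple[float, float]:
    """Channel-level saturation thresholds (lower, upper) in µV.

    Uses ``sat_fraction`` of the amplifier operating limits when known,
    otherwise of the channel's maximum absolute voltage (computed over the
    whole channel, not per trial, so artifact-free trials cannot misfire).
    """
    if recording.amp_limits is not None:
        lo, hi = recording.amp_limits
        return cfg.sat_fraction * lo, cfg.sat_fraction * hi
    peak = float(np.max(np.abs(recording.samples))) if recording.n_samples \
        else 0.0
    thr = cfg.sat_fraction * peak
    return -thr, thr


def find_recovery_start(trial: np.ndarray, cfg: LogLiraConfig, fs: float,
                        sat_lo: float, sat_hi: float,
                        scan_end: Optional[int] = None
                        ) -> tuple[int, float, bool]:
    """Locate ``n_s``, the first recoverable sample, and the blanking period.

    ``n_s`` is the first sample after the default blanking interval or, if
    saturation persists beyond it, the first non-saturated sample. Multiple
    saturated stretches are concatenated: ``n_s`` follows the last one. The
    scan is limited to ``scan_end`` (defaults to the transient region) so a
    late large excursion cannot blank a whole trial. Returns
    ``(n_s, beta_ms, saturated)``.
    """
    N = trial.size
    b0 = min(ms_to_samples(cfg.beta0_ms, fs), N)
    if scan_end is None:
        scan_end = N
    scan_end = min(scan_end, N)
    seg = trial[:scan_end]
    sat = (seg >= sat_hi) | (seg <= sat_lo)
    saturated = bool(np.any(sat))
    if not saturated:
        return b0, b0 / fs * 1e3, False
    last_sat = int(np.nonzero(sat)[0][-1])
    n_s = max(b0, last_sat + 1)
    if n_s >= N:
        return N, N / fs * 1e3, True
    return n_s, n_s / fs * 1e3, True


def estimate_artifact(trial: np.ndarray, grid: LogGrid, n_s: int,
                      n_e: int) -> np.ndarray:
    """Piecewise-linear artifact estimate over [n_s, n_e).

    Node values are neighborhood means of the trial; the blanked portion
    [0, n_s) is pasted without modification; beyond ``n_e`` the estimate is
    zero so subtraction leaves that region untouched. The interpolant is
    anchored at ``n_e`` on the raw signal so the residual is continuous at
    the recovery end.
    """
    if grid.n_points == 0:
        raise ValueError("empty interpolation grid")
    N = trial.size
    artifact = np.zeros(N)
    artifact[:n_s] = trial[:n_s]
    xs = grid.nodes.astype(np.float64)
    ys = np.array([neighborhood_mean(trial, n, e, lo=n_s, hi=n_e)
                   for n, e in zip(grid.nodes, grid.eps)])
    anchor = min(n_e, N - 1)
    if anchor > xs[-1]:
        xs = np.append(xs, anchor)
        ys = np.append(ys, trial[anchor])
    span = np.arange(n_s, n_e)
    artifact[n_s:n_e] = np.interp(span, xs, ys)
    return artifact


def subtract_and_bridge(trial: np.ndarray, artifact: np.ndarray, n_s: int,
                        n_e: int, pre_value: float) -> np.ndarray:
    """Subtract the artifact estimate and bridge the blanked region.

    A line is traced from the sample preceding the stimulation onset
    (``pre_value``, at virtual index -1) to the sample following ``n_e``.
    The blanked region takes the line's values; the recovered residual on
    [n_s, n_e) is superimposed on the line; the region from the line's end
    onward is untouched.
    """
    N = trial.size
    clean = trial - artifact
    x_end = min(n_e, N - 1)
    if x_end < 0:
        return trial.copy()
    end_value = trial[x_end]
    idx = np.arange(x_end)
    line = pre_value + (end_value - pre_value) * (idx + 1) / (x_end + 1)
    out = trial.copy()
    out[:n_s] = line[:n_s]
    stop = min(n_e, x_end)
    out[n_s:stop] = clean[n_s:stop] + line[n_s:stop]
    return out


def blank_only(trial: np.ndarray, n_blank: int, pre_value: float
               ) -> np.ndarray:
    """Replace the first ``n_blank`` samples with a bridging line; leave the
    rest untouched (the no-transient path)."""
    N = trial.size
    out = trial.copy()
    if n_blank <= 0:
        return out
    if n_blank >= N:
        out[:] = np.linspace(pre_value, pre_value, N)
        return out
    end_value = trial[n_blank]
    idx = np.arange(n_blank)
    out[:n_blank] = pre_value + (end_value - pre_value) * (idx + 1) / (n_blank + 1)
    return out


def clean_trial(trial: np.ndarray, pre_window: np.ndarray, pre_value: float,
                cfg: LogLiraConfig, fs: float, sat_lo: float, sat_hi: float
                ) -> tuple[np.ndarray, TrialArtifactFit]:
    """Run the full stage-1 pipeline on one trial."""
    N = trial.size
    b0 = min(ms_to_samples(cfg.beta0_ms, fs), N)
    scan_limit = min(N, ms_to_samples(cfg.grid_span_ms, fs))

    transient = detect_transient(trial, pre_window, cfg, fs)
    if not transient:
        fit = TrialArtifactFit(beta_ms=b0 / fs * 1e3, n_s=b0, n_e=b0,
                               artifact=None, transient=False,
                               saturated=False)
        return blank_only(trial, b0, pre_value), fit

    n_e = find_transient_end(trial, cfg, fs, start=b0)
    n_s, beta_ms, saturated = find_recovery_start(
        trial, cfg, fs, sat_lo, sat_hi, scan_end=min(n_e, scan_limit))
    if n_s >= N:  # whole trial saturated / blanked
        fit = TrialArtifactFit(beta_ms=beta_ms, n_s=N, n_e=N, artifact=None,
                               transient=True, saturated=saturated)
        return blank_only(trial, N, pre_value), fit
    n_e = max(n_e, n_s)

    grid = build_log_grid(cfg, fs, n_s, n_e)
    if grid.n_points == 0 or n_e <= n_s:
        # nothing to interpolate: blanking-only treatment
        fit = TrialArtifactFit(beta_ms=beta_ms, n_s=n_s, n_e=n_s,
                               artifact=None, transient=True,
                               saturated=saturated)
        return blank_only(trial, n_s, pre_value), fit

    artifact = estimate_artifact(trial, grid, n_s, n_e)
    clean = subtract_and_bridge(trial, artifact, n_s, n_e, pre_value)
    fit = TrialArtifactFit(beta_ms=beta_ms, n_s=n_s, n_e=n_e,
                           artifact=artifact, transient=True,
                           saturated=saturated)
    return clean, fit


def clean_channel(recording: Recording, stims: StimTrain,
                  cfg: Optional[LogLiraConfig] = None,
                  run_secondary: bool = True
                  ) -> tuple[Recording, list[TrialArtifactFit]]:
    """Suppress every stimulation artifact in a channel.

    Applies the stage-1 pipeline trial by trial (the pre-first-onset prefix
    is passed through untouched), then hands the cleaned trials to the
    secondary-artifact mitigation stage. Per-trial failures are downgraded
    to warnings; the rest of the channel is still processed.
    """
    from .secondary import mitigate_secondary  # local import: avoid cycle

    cfg = cfg or LogLiraConfig()
    out = recording.samples.copy()
    if stims.K == 0:
        return Recording(out, recording.fs, recording.amp_limits,
                         recording.channel_id), []

    fs = recording.fs
    trialset = segment_trials(recording, stims)
    sat_lo, sat_hi = saturation_thresholds(recording, cfg)
    w_pre = ms_to_samples(cfg.transient_window_ms, fs)
    fits: list[TrialArtifactFit] = []
    bounds = np.append(stims.onsets, recording.n_samples)

    prev_end_abs = -1  # absolute sample of previous trial's n_e
    for i in range(trialset.K):
        onset = int(stims.onsets[i])
        trial = trialset.trials[i]
        pre_window = recording.samples[max(onset - w_pre, 0):onset]
        pre_value = float(out[onset - 1]) if onset > 0 else \
            (float(trial[0]) if trial.size else 0.0)
        try:
            clean, fit = clean_trial(trial, pre_window, pre_value, cfg, fs,
                                     sat_lo, sat_hi)
            fit.pre_window_overlap = onset - w_pre < prev_end_abs
            out[onset:bounds[i + 1]] = clean
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"trial {i} (onset {onset}) failed: {exc}; "
                          "left unmodified")
            fit = TrialArtifactFit(beta_ms=0.0, n_s=0, n_e=0, artifact=None,
                                   transient=False, saturated=False)
        fits.append(fit)
        prev_end_abs = onset + fit.n_e

    if run_secondary:
        mitigate_secondary(out, stims, fits, cfg, fs)

    return Recording(out, fs, recording.amp_limits,
                     recording.channel_id), fits


def fits_to_dataframe(fits: list[TrialArtifactFit],
                      stims: StimTrain) -> pd.DataFrame:
    """Tabular per-trial fit metadata for export."""
    return pd.DataFrame({
        "trial": np.arange(len(fits)),
        "onset": stims.onsets[:len(fits)],
        "beta_ms": [f.beta_ms for f in fits],
        "n_s": [f.n_s for f in fits],
        "n_e": [f.n_e for f in fits],
        "transient": [f.transient for f in fits],
        "saturated": [f.saturated for f in fits],
    })
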