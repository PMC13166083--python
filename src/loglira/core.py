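"""Domain types and trial segmentation.

A continuous extracellular recording is carved into *trials*: the half-open
stretches ``[onset_i, onset_{i+1})`` following each stimulation onset (the
last trial extends to the end of the recording). Everything downstream —
artifact estimation, secondary mitigation, the baseline suppressors — works
on these per-trial segments, so segmentation must be an exact partition of
the recording past the first onset.

Sample indexing is 0-based throughout and durations configured in
milliseconds are converted to samples by ``round(ms * 1e-3 * fs)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np


@dataclass
class Recording:
    """A single-channel continuous voltage trace.

    Parameters
    ----------
    samples : ndarray
        Voltage series in µV.
    fs : float
        Sampling rate in Hz.
    amp_limits : (float, float), optional
        Lower and upper amplifier operating limits in µV. When the
        recording clips, it clips at these values.
    channel_id : str
        Opaque channel label carried through to reports.
    """

    samples: np.ndarray
    fs: float
    amp_limits: Optional[tuple[float, float]] = None
    channel_id: str = "ch0"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError("fs must be > 0")
        if self.amp_limits is not None:
            lo, hi = self.amp_limits
            if not lo < hi:
                raise ValueError("amp_limits must satisfy lower < upper")
            self.amp_limits = (float(lo), float(hi))
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.n_samples / self.fs

    def copy(self) -> "Recording":
        return Recording(self.samples.copy(), self.fs, self.amp_limits,
                         self.channel_id)


@dataclass
class StimTrain:
    """Strictly increasing stimulation onset indices (samples)."""

    onsets: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.int64)
        if self.onsets.ndim != 1:
            raise ValueError("onsets must be one-dimensional")
        if self.onsets.size and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if self.onsets.size and self.onsets[0] < 0:
            raise ValueError("onsets must be non-negative")

    @property
    def K(self) -> int:
        return int(self.onsets.size)

    def __len__(self) -> int:
        return self.K


@dataclass
class TrialSet:
    """The K per-stimulus segments carved from a recording."""

    trials: list[np.ndarray]
    onsets: np.ndarray
    fs: float

    @property
    def K(self) -> int:
        return len(self.trials)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([t.size for t in self.trials], dtype=np.int64)

    def onset_of(self, i: int) -> int:
        return int(self.onsets[i])


def segment_trials(recording: Recording, stims: StimTrain) -> TrialSet:
    """Carve a recording into per-stimulus trials.

    Trial ``i`` is the half-open slice ``[onset_i, onset_{i+1})``; the last
    trial runs to the end of the recording. Concatenating the pre-first-onset
    prefix with all trials reconstructs the recording exactly.
    """
    if stims.K == 0:
        raise ValueError("stimulus train is empty")
    if stims.onsets[-1] >= recording.n_samples:
        raise ValueError(
            f"onset {int(stims.onsets[-1])} beyond recording end "
            f"({recording.n_samples} samples)")
    bounds = np.append(stims.onsets, recording.n_samples)
    trials = [recording.samples[bounds[i]:bounds[i + 1]]
              for i in range(stims.K)]
    return TrialSet(trials=trials, onsets=stims.onsets.copy(),
                    fs=recording.fs)


def rejoin_trials(prefix: np.ndarray, trials: Sequence[np.ndarray]) -> np.ndarray:
    """Inverse of :func:`segment_trials`: prefix + trials -> full trace."""
    return np.concatenate([prefix, *trials])


def iai_of(stims: StimTrain, fs: float) -> np.ndarray:
    """Inter-artifact intervals (seconds) of a stimulus train.

    Requires at least two onsets; the mean artifact rate is the reciprocal
    of the median of this series.
    """
    if stims.K < 2:
        raise ValueError("at least two onsets are required to form IAIs")
    return np.diff(stims.onsets) / float(fs)


def mean_artifact_rate(stims: StimTrain, fs: float) -> float:
    """MAR = 1 / median(IAI), in Hz."""
    return 1.0 / float(np.median(iai_of(stims, fs)))
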