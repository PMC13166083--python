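"""Artifact suppressors behind a common interface.

Every suppressor consumes a recording plus its stimulus train and returns a
recording of identical length together with per-trial blanking metadata, so
the evaluation harness runs unchanged over all of them. Besides logLIRA,
two simple reference methods are provided: dynamic averaging (template =
mean of temporally adjacent trials) and global polynomial fitting (per-trial
least-squares polynomial over a fixed span). An external command can be
plugged in through a file-based contract.
"""

from __future__ import annotations

import subprocess
import tempfile
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as lio
from .config import LogLiraConfig, ms_to_samples
from .core import Recording, StimTrain, segment_trials
from .estimation import blank_only, clean_channel, fits_to_dataframe


class Suppressor:
    """Interface: ``clean(recording, stims) -> (Recording, DataFrame)``.

    The metadata frame carries at least columns ``trial`` and ``blank_ms``
    (per-trial discarded interval).
    """

    name = "identity"

    def clean(self, recording: Recording, stims: StimTrain
              ) -> tuple[Recording, pd.DataFrame]:
        meta = pd.DataFrame({"trial": np.arange(stims.K),
                             "blank_ms": np.zeros(stims.K)})
        return recording.copy(), meta


class LogLira(Suppressor):
    """The two-stage log-interpolation suppressor."""

    name = "loglira"

    def __init__(self, cfg: Optional[LogLiraConfig] = None,
                 run_secondary: bool = True):
        self.cfg = cfg or LogLiraConfig()
        self.run_secondary = run_secondary

    def clean(self, recording, stims):
        clean_rec, fits = clean_channel(recording, stims, self.cfg,
                                        run_secondary=self.run_secondary)
        meta = fits_to_dataframe(fits, stims)
        meta["blank_ms"] = meta["beta_ms"]
        return clean_rec, meta


def _neighbor_window(i: int, K: int, n: int) -> range:
    """Indices of the n temporally nearest trials to trial i (self
    included, ties toward earlier trials): a contiguous window around i,
    shifted inward at the edges."""
    left = n // 2
    lo = i - left
    hi = lo + n
    if lo < 0:
        lo, hi = 0, n
    elif hi > K:
        lo, hi = K - n, K
    return range(lo, hi)


class DynamicAveraging(Suppressor):
    """Template subtraction using temporally adjacent artifacts.

    The template for stimulus i is the mean of the ``n_neighbors``
    temporally nearest trials (the trial itself included, ties broken
    toward earlier trials), truncated to the shortest trial involved. A
    fixed blanking interval is discarded and bridged linearly.
    """

    name = "dynavg"

    def __init__(self, n_neighbors: int = 10, blank_ms: float = 1.0,
                 subtract_span_ms: Optional[float] = None):
        self.n_neighbors = n_neighbors
        self.blank_ms = blank_ms
        self.subtract_span_ms = subtract_span_ms  # None: whole trial

    def clean(self, recording, stims):
        fs = recording.fs
        out = recording.samples.copy()
        if stims.K == 0:
            return Recording(out, fs, recording.amp_limits,
                             recording.channel_id), pd.DataFrame(
                                 {"trial": [], "blank_ms": []})
        trialset = segment_trials(recording, stims)
        K = trialset.K
        n_nb = self.n_neighbors
        if K <= n_nb:
            warnings.warn("fewer trials than n_neighbors: falling back to "
                          "the global average template")
            n_nb = K
        blank = ms_to_samples(self.blank_ms, fs)
        span_cap = (ms_to_samples(self.subtract_span_ms, fs)
                    if self.subtract_span_ms else None)
        bounds = np.append(stims.onsets, recording.n_samples)
        for i in range(K):
            chosen = _neighbor_window(i, K, n_nb)
            L = min(trialset.trials[j].size for j in chosen)
            if span_cap is not None:
                L = min(L, span_cap)
            template = np.mean([trialset.trials[j][:L] for j in chosen],
                               axis=0)
            onset = int(stims.onsets[i])
            out[onset:onset + L] -= template
            pre = float(out[onset - 1]) if onset > 0 else 0.0
            seg = out[onset:bounds[i + 1]]
            out[onset:bounds[i + 1]] = blank_only(seg, min(blank, seg.size),
                                                  pre)
        meta = pd.DataFrame({"trial": np.arange(K),
                             "blank_ms": np.full(K, self.blank_ms)})
        return Recording(out, fs, recording.amp_limits,
                         recording.channel_id), meta


class GlobalPolyfit(Suppressor):
    """Per-trial least-squares polynomial artifact fit.

    A polynomial of the given order is fit to the post-blanking span of
    each trial and subtracted over that span; the remainder of the trial is
    untouched. Trials with fewer samples than ``order + 1`` are skipped.
    """

    name = "polyfit"

    def __init__(self, order: int = 8, fit_span_ms: float = 10.0,
                 blank_ms: float = 0.5):
        if order < 1:
            raise ValueError("order must be >= 1")
        self.order = order
        self.fit_span_ms = fit_span_ms
        self.blank_ms = blank_ms

    def clean(self, recording, stims):
        fs = recording.fs
        out = recording.samples.copy()
        if stims.K == 0:
            return Recording(out, fs, recording.amp_limits,
                             recording.channel_id), pd.DataFrame(
                                 {"trial": [], "blank_ms": []})
        trialset = segment_trials(recording, stims)
        blank = ms_to_samples(self.blank_ms, fs)
        span = ms_to_samples(self.fit_span_ms, fs)
        bounds = np.append(stims.onsets, recording.n_samples)
        for i in range(trialset.K):
            trial = trialset.trials[i]
            onset = int(stims.onsets[i])
            a, b = min(blank, trial.size), min(blank + span, trial.size)
            if b - a < self.order + 1:
                warnings.warn(f"trial {i}: too short for order "
                              f"{self.order} fit; skipped")
                continue
            x = np.linspace(-1.0, 1.0, b - a)
            coefs = np.polynomial.polynomial.polyfit(x, trial[a:b],
                                                     self.order)
            out[onset + a:onset + b] -= \
                np.polynomial.polynomial.polyval(x, coefs)
            pre = float(out[onset - 1]) if onset > 0 else 0.0
            seg = out[onset:bounds[i + 1]]
            out[onset:bounds[i + 1]] = blank_only(seg, min(blank, seg.size),
                                                  pre)
        K = trialset.K
        meta = pd.DataFrame({"trial": np.arange(K),
                             "blank_ms": np.full(K, self.blank_ms)})
        return Recording(out, fs, recording.amp_limits,
                         recording.channel_id), meta


class ExternalCommand(Suppressor):
    """Plug-in contract for suppressors implemented outside this package.

    The harness writes the recording and onset files into a temporary
    directory, substitutes their paths (and an output path) into the user
    command, runs it, and reads back a cleaned recording of identical
    length. The command template must contain ``{recording}``, ``{onsets}``
    and ``{output}`` placeholders.
    """

    def __init__(self, command: str, name: str = "external"):
        self.command = command
        self.name = name

    def clean(self, recording, stims):
        with tempfile.TemporaryDirectory() as tmp:
            tmp = Path(tmp)
            rec_path, on_path = tmp / "rec.f32", tmp / "onsets.txt"
            out_path = tmp / "clean.f32"
            lio.write_recording(rec_path, recording)
            lio.write_event_train(on_path, stims.onsets, recording.fs)
            cmd = self.command.format(recording=rec_path, onsets=on_path,
                                      output=out_path)
            subprocess.run(cmd, shell=True, check=True)
            clean = lio.read_recording(out_path)
        if clean.n_samples != recording.n_samples:
            raise ValueError("external suppressor returned a recording of "
                             "different length")
        meta_path = out_path.with_suffix(".meta.csv")
        meta = (pd.read_csv(meta_path) if meta_path.exists()
                else pd.DataFrame({"trial": np.arange(stims.K),
                                   "blank_ms": np.full(stims.K, np.nan)}))
        return clean, meta


def get_suppressor(name: str, cfg: Optional[LogLiraConfig] = None
                   ) -> Suppressor:
    """Dispatch by name: loglira, dynavg, polyfit, identity, external:<cmd>."""
    if name == "loglira":
        return LogLira(cfg)
    if name == "dynavg":
        return DynamicAveraging()
    if name == "polyfit":
        return GlobalPolyfit()
    if name == "identity":
        return Suppressor()
    if name.startswith("external:"):
        return ExternalCommand(name.split(":", 1)[1])
    raise ValueError(f"unknown suppressor {name!r}; available: loglira, "
                     "dynavg, polyfit, identity, external:<cmd>")
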