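"""File formats: recordings, event trains, manifests.

Recordings travel as raw little-endian binary (float32, or int16 with a
scale factor) plus a JSON sidecar holding the sampling rate, units and
amplifier limits; tiny toy cases may use a one-voltage-per-line text file
instead. Stimulus onsets and spike trains are one integer sample index per
line with a ``# fs=<Hz>`` header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core import Recording, StimTrain


def write_recording(path: str | Path, rec: Recording,
                    dtype: str = "float32", scale: float = 1.0) -> None:
    """Write a recording as raw binary + JSON sidecar.

    ``dtype`` may be ``float32`` or ``int16``; for int16 the stored value is
    ``round(µV / scale)``.
    """
    path = Path(path)
    if dtype == "float32":
        data = rec.samples.astype("<f4")
    elif dtype == "int16":
        data = np.round(rec.samples / scale).astype("<i2")
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    data.tofile(path)
    sidecar = {
        "fs": rec.fs,
        "units": "uV",
        "dtype": dtype,
        "scale": scale,
        "amp_limits": list(rec.amp_limits) if rec.amp_limits else None,
        "channel_id": rec.channel_id,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1))


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    dtype = sidecar.get("dtype", "float32")
    if dtype == "float32":
        samples = np.fromfile(path, dtype="<f4").astype(np.float64)
    elif dtype == "int16":
        samples = np.fromfile(path, dtype="<i2").astype(np.float64)
        samples *= float(sidecar.get("scale", 1.0))
    else:
        raise ValueError(f"unsupported dtype {dtype!r} in sidecar")
    limits = sidecar.get("amp_limits")
    return Recording(samples, fs=float(sidecar["fs"]),
                     amp_limits=tuple(limits) if limits else None,
                     channel_id=sidecar.get("channel_id", "ch0"))


def write_recording_text(path: str | Path, rec: Recording) -> None:
    """One voltage per line, with a header carrying fs. Toy cases only."""
    header = f"fs={rec.fs}"
    np.savetxt(path, rec.samples, fmt="%.6f", header=header)


def read_recording_text(path: str | Path) -> Recording:
    path = Path(path)
    fs = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "fs=" in first:
        fs = float(first.split("fs=")[1].strip())
    if fs is None:
        raise ValueError(f"{path}: missing '# fs=<Hz>' header")
    samples = np.loadtxt(path)
    return Recording(np.atleast_1d(samples), fs=fs)


def write_event_train(path: str | Path, events: np.ndarray, fs: float) -> None:
    """Stimulus onsets or spike times: one integer sample per line."""
    events = np.asarray(events, dtype=np.int64)
    with open(path, "w") as fh:
        fh.write(f"# fs={fs}\n")
        for e in events:
            fh.write(f"{int(e)}\n")


def read_event_train(path: str | Path) -> tuple[np.ndarray, float]:
    """Returns (events, fs)."""
    path = Path(path)
    fs = None
    events = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "fs=" in line:
                    fs = float(line.split("fs=")[1].strip())
                continue
            try:
                events.append(int(line))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: not an integer sample "
                                 f"index: {line!r}") from exc
    if fs is None:
        raise ValueError(f"{path}: missing '# fs=<Hz>' header")
    return np.asarray(events, dtype=np.int64), fs


def read_stim_train(path: str | Path) -> tuple[StimTrain, float]:
    events, fs = read_event_train(path)
    return StimTrain(events), fs


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
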