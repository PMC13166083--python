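"""Secondary-artifact mitigation (stage 2).

Piecewise-linear interpolation can leave small deterministic residuals in
the first couple of milliseconds after the blanking interval, where the
voltage changes steepest; after bandpass filtering these look like spikes.
Because the interpolation is deterministic, those residuals are nearly
identical across trials with similar artifact shapes, while genuine neural
activity is not time-locked to the onset. Clustering the 2 ms post-blanking
windows of all trials and subtracting each large cluster's mean therefore
removes the shared residual and largely spares the activity.

The windows are embedded to two dimensions with UMAP (correlation metric,
so only waveform shape matters, not scale) and grouped with a density-based
clusterer that needs no preset cluster count and is noise-aware. Clusters
with fewer than ``theta`` members are discarded: their means would be too
contaminated by neural activity to subtract safely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import LogLiraConfig, ms_to_samples
from .core import StimTrain
from .estimation import TrialArtifactFit

_ZERO_VAR_COORD = 1e6  # parking coordinate for zero-variance rows


@dataclass
class PostBlankWindowSet:
    """K x w matrix of post-blanking windows plus a validity mask.

    Row i starts at trial i's own recovery start ``n_s`` (not at a global
    offset); rows from trials too short to hold a full window are masked.
    """

    windows: np.ndarray
    valid: np.ndarray
    starts: np.ndarray  # per-trial window start, relative to onset

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class ClusterAssignment:
    """Per-trial cluster labels over the window set.

    ``labels[i] == -1`` marks noise or masked trials; ``retained`` lists the
    cluster ids with at least ``theta`` members.
    """

    labels: np.ndarray
    embedding: Optional[np.ndarray]
    retained: list[int]


def extract_windows(out: np.ndarray, stims: StimTrain,
                    fits: list[TrialArtifactFit], cfg: LogLiraConfig,
                    fs: float) -> PostBlankWindowSet:
    """Collect the 2 ms windows following each trial's blanking interval."""
    w = ms_to_samples(cfg.secondary_window_ms, fs)
    K = len(fits)
    bounds = np.append(stims.onsets, out.size)
    windows = np.zeros((K, w))
    valid = np.zeros(K, dtype=bool)
    starts = np.zeros(K, dtype=np.int64)
    for i, fit in enumerate(fits):
        if not cfg.include_quiet_trials and not fit.transient:
            continue
        start = int(stims.onsets[i]) + fit.n_s
        stop = start + w
        starts[i] = fit.n_s
        if stop <= bounds[i + 1]:
            windows[i] = out[start:stop]
            valid[i] = True
    return PostBlankWindowSet(windows=windows, valid=valid, starts=starts)


def embed_windows(windows: np.ndarray, cfg: LogLiraConfig,
                  seed: Optional[int] = None) -> np.ndarray:
    """2-D UMAP embedding of the window rows, correlation metric.

    Deterministic for a fixed seed. Rows with zero variance (for which the
    correlation distance is undefined) are parked at a constant coordinate
    far from the data and excluded from the manifold computation.
    """
    import umap  # deferred: numba compilation is slow at import time

    n = windows.shape[0]
    if n < 2:
        raise ValueError("need at least 2 windows to embed")
    seed = cfg.seed if seed is None else seed
    var = windows.std(axis=1)
    ok = var > 0
    coords = np.full((n, 2), _ZERO_VAR_COORD)
    n_ok = int(ok.sum())
    if n_ok < 2:
        return coords
    if n_ok < 4:
        # too few points for a manifold layout: deterministic 1-D
        # placement by cumulative correlation distance to the first row
        from scipy.spatial.distance import cdist
        d = cdist(windows[ok], windows[ok][:1],
                  metric="correlation").ravel()
        coords[ok] = np.column_stack([d, np.zeros_like(d)])
        return coords
    n_neighbors = min(cfg.umap_neighbors, n_ok - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_components=2, metric="correlation",
                            n_neighbors=max(n_neighbors, 2),
                            min_dist=cfg.umap_min_dist,
                            random_state=seed, n_jobs=1)
        coords[ok] = reducer.fit_transform(windows[ok])
    return coords


def _density_mode_labels(pts: np.ndarray, merge_ratio: float,
                         grid_size: int) -> np.ndarray:
    """Mode-seeking labels by kernel-density hill climbing.

    The density of the 2-D points is estimated on a regular grid; each grid
    cell is assigned to the local maximum reached by steepest ascent, and
    two modes are merged when the saddle between them is high relative to
    the smaller peak (saddle >= merge_ratio * min(peaks)), so shallow
    valleys inside one noisy blob do not split it. Every point inherits the
    basin of its cell.
    """
    from scipy.stats import gaussian_kde

    n = pts.shape[0]
    if n < 3 or np.allclose(pts, pts[0]):
        return np.zeros(n, dtype=np.int64)
    try:
        kde = gaussian_kde(pts.T)
    except np.linalg.LinAlgError:  # degenerate geometry: one cluster
        return np.zeros(n, dtype=np.int64)
    G = grid_size
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    pad = 0.05 * np.maximum(hi - lo, 1e-9)
    lo, hi = lo - pad, hi + pad
    gx = np.linspace(lo[0], hi[0], G)
    gy = np.linspace(lo[1], hi[1], G)
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(G, G)

    # steepest-ascent pointer: each cell points at its densest 3x3 neighbor
    padded = np.full((G + 2, G + 2), -np.inf)
    padded[1:-1, 1:-1] = dens
    best = np.full((G, G), -np.inf)
    ptr = np.zeros((G, G), dtype=np.int64)
    cell_idx = np.arange(G * G).reshape(G, G)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            nb = padded[1 + di:G + 1 + di, 1 + dj:G + 1 + dj]
            take = nb > best
            best = np.where(take, nb, best)
            shifted = np.roll(np.roll(cell_idx, -di, axis=0), -dj, axis=1)
            ptr = np.where(take, shifted, ptr)
    ptr = ptr.ravel()
    # chase pointers to the basin peak (converges in <= grid diameter)
    for _ in range(2 * G):
        nxt = ptr[ptr]
        if np.array_equal(nxt, ptr):
            break
        ptr = nxt
    basin = ptr  # cell -> peak cell id

    # persistence merge: sweep cells by decreasing density; when a cell
    # touches a higher-density cell of another basin, the cell's density
    # is the saddle between the two modes
    parent = {int(p): int(p) for p in np.unique(basin)}
    peak = {int(p): float(dens.ravel()[p]) for p in parent}

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    flat = dens.ravel()
    order = np.argsort(flat)[::-1]
    seen = np.zeros(G * G, dtype=bool)
    for c in order:
        i, j = divmod(int(c), G)
        seen[c] = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                ii, jj = i + di, j + dj
                if not (0 <= ii < G and 0 <= jj < G):
                    continue
                d = ii * G + jj
                if not seen[d]:
                    continue
                ra, rb = find(int(basin[c])), find(int(basin[d]))
                if ra == rb:
                    continue
                saddle = float(flat[c])
                if saddle >= merge_ratio * min(peak[ra], peak[rb]):
                    keep, drop = (ra, rb) if peak[ra] >= peak[rb] \
                        else (rb, ra)
                    parent[drop] = keep
    roots = sorted({find(int(b)) for b in basin})
    root_id = {r: k for k, r in enumerate(roots)}

    ci = np.clip(np.searchsorted(gx, pts[:, 0]) - 0, 0, G - 1)
    cj = np.clip(np.searchsorted(gy, pts[:, 1]) - 0, 0, G - 1)
    labels = np.array([root_id[find(int(basin[a * G + b]))]
                       for a, b in zip(ci, cj)], dtype=np.int64)
    return labels


def cluster_density(embedding: np.ndarray, theta: int,
                    merge_ratio: float = 0.5,
                    grid_size: int = 64) -> ClusterAssignment:
    """Density-based clustering of the 2-D embedding.

    Mode-seeking on a kernel density estimate (no preset number of
    clusters); clusters with fewer than ``theta`` members are moved to
    noise. Parked zero-variance points never join a cluster.
    """
    n = embedding.shape[0]
    labels = np.full(n, -1, dtype=np.int64)
    ok = np.abs(embedding[:, 0]) < _ZERO_VAR_COORD
    pts = embedding[ok]
    if pts.shape[0] >= 2:
        labels[ok] = _density_mode_labels(pts, merge_ratio, grid_size)
    retained = []
    for cid in np.unique(labels):
        if cid == -1:
            continue
        if int(np.sum(labels == cid)) >= theta:
            retained.append(int(cid))
        else:
            labels[labels == cid] = -1
    return ClusterAssignment(labels=labels, embedding=embedding,
                             retained=retained)


def subtract_cluster_means(out: np.ndarray, stims: StimTrain,
                           window_set: PostBlankWindowSet,
                           assignment: ClusterAssignment) -> np.ndarray:
    """Subtract each retained cluster's mean window from its member trials.

    Modifies ``out`` in place over each member trial's [n_s, n_s + w) span
    only; noise-labelled and masked trials are untouched. Returns the
    per-cluster mean waveforms (one row per retained cluster).
    """
    w = window_set.windows.shape[1]
    means = []
    for cid in assignment.retained:
        members = np.nonzero((assignment.labels == cid)
                             & window_set.valid)[0]
        if members.size == 0:
            continue
        mean_wave = window_set.windows[members].mean(axis=0)
        means.append(mean_wave)
        for i in members:
            start = int(stims.onsets[i]) + int(window_set.starts[i])
            out[start:start + w] -= mean_wave
    return np.array(means) if means else np.empty((0, w))


def mitigate_secondary(out: np.ndarray, stims: StimTrain,
                       fits: list[TrialArtifactFit], cfg: LogLiraConfig,
                       fs: float) -> Optional[ClusterAssignment]:
    """Run the full stage-2 pipeline in place on a cleaned trace.

    With fewer than ``theta`` usable trials no cluster can reach the
    retention threshold, so the stage is the identity and the embedding is
    skipped entirely.
    """
    window_set = extract_windows(out, stims, fits, cfg, fs)
    if window_set.n_valid < cfg.theta:
        return None
    embedding = embed_windows(window_set.windows[window_set.valid], cfg)
    full = np.full((len(fits), 2), _ZERO_VAR_COORD)
    full[window_set.valid] = embedding
    labels_assign = cluster_density(full, cfg.theta)
    # masked rows must stay noise even if parked coordinates coincide
    labels_assign.labels[~window_set.valid] = -1
    subtract_cluster_means(out, stims, window_set, labels_assign)
    return labels_assign
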