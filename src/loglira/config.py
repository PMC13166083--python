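"""Configuration for the logLIRA suppression pipeline."""

from __future__ import annotations

from dataclasses import dataclass, asdict


def ms_to_samples(ms: float, fs: float) -> int:
    """Convert a duration in milliseconds to samples, rounding to nearest."""
    return int(round(ms * 1e-3 * fs))


@dataclass
class LogLiraConfig:
    """Tunable parameters of the two-stage artifact suppression pipeline.

    All durations are expressed in milliseconds so that the configuration is
    independent of the acquisition system's sampling rate; they are converted
    to samples with :func:`ms_to_samples` at run time.

    Parameters
    ----------
    beta0_ms : float
        Default blanking period after each stimulus onset. The initial
        portion of every trial is considered unrecoverable and discarded.
    grid_points : int
        Number of interpolation points ``P`` of the logarithmic grid.
    grid_span_ms : float
        Span ``T`` of the grid: points cover 0 .. T-1 ms before shifting.
    settling_ms : float
        Settling time after which the trial is assumed to have reached its
        steady state; the steady-state median is computed beyond this point.
    steady_tol_uv : float
        Tolerance (µV) for the moving-average / steady-state-median
        intersection that marks the artifact transient's end.
    sat_fraction : float
        Fraction of the amplifier operating limit (or of the channel's
        maximum absolute voltage when limits are unknown) above which a
        sample is considered saturated.
    transient_window_ms : float
        Length of the two windows compared to decide whether a trial
        contains a significant artifact transient, and of the moving-average
        filter used to locate the transient's end.
    secondary_window_ms : float
        Length of the post-blanking window clustered during secondary
        artifact mitigation.
    theta : int
        Minimum cluster membership for a secondary-artifact cluster to have
        its mean subtracted.
    transient_mean_k : float
        "Similar enough" criterion: no transient is declared when the
        post-window mean deviates from the pre-window mean by at most
        ``transient_mean_k`` pre-window standard deviations ...
    transient_std_ratio : tuple of float
        ... and the post/pre standard-deviation ratio lies in this interval.
    epsilon_cap : float
        The neighborhood half-width at grid point j is derived from the
        local grid pitch and capped at ``epsilon_cap`` times the forward
        spacing, so neighborhoods never swallow distant nodes.
    umap_neighbors, umap_min_dist : embedding parameters for the secondary
        stage (correlation metric is fixed).
    include_quiet_trials : bool
        Whether windows from trials without a detected transient enter the
        secondary-artifact clustering. Off by default so that a channel
        with no artifacts is only ever modified inside its blanking
        windows.
    seed : int
        Seed for every stochastic component (embedding layout).
    """

    beta0_ms: float = 1.0
    grid_points: int = 42
    grid_span_ms: float = 50.0
    settling_ms: float = 40.0
    steady_tol_uv: float = 1.0
    sat_fraction: float = 0.95
    transient_window_ms: float = 5.0
    secondary_window_ms: float = 2.0
    theta: int = 20
    transient_mean_k: float = 2.0
    transient_std_ratio: tuple[float, float] = (0.5, 2.0)
    epsilon_cap: float = 2.0
    umap_neighbors: int = 15
    umap_min_dist: float = 0.1
    include_quiet_trials: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_points < 2:
            raise ValueError("grid_points must be >= 2")
        if self.grid_span_ms <= 1:
            raise ValueError("grid_span_ms must be > 1 ms")
        if not (0 < self.sat_fraction <= 1):
            raise ValueError("sat_fraction must be in (0, 1]")
        if self.theta < 1:
            raise ValueError("theta must be >= 1")
        for name in ("beta0_ms", "settling_ms", "steady_tol_uv",
                     "transient_window_ms", "secondary_window_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["transient_std_ratio"] = list(self.transient_std_ratio)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LogLiraConfig":
        d = dict(d)
        if "transient_std_ratio" in d:
            d["transient_std_ratio"] = tuple(d["transient_std_ratio"])
        return cls(**d)
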