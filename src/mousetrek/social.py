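"""Two-animal interaction metrics: interval distance, its CDF, K-S comparison.

The *interval distance* is the per-frame Euclidean distance between the two
animals' centers of mass; its empirical distribution over a session (the
"accumulation curve") summarizes how closely the animals kept company, and
two sessions are compared with the two-sample Kolmogorov-Smirnov test.
Frame-wise distances are strongly autocorrelated, so the test is run on a
temporally strided subsample; a stride of one frame reproduces the naive
frame-level procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .kinematics import Trajectory


@dataclass
class IntervalSeries:
    """Per-frame inter-animal distance in cm (NaN where either animal is missing)."""

    distances: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        finite = self.distances[np.isfinite(self.distances)]
        if finite.size and finite.min() < 0:
            raise ValueError("distances must be non-negative")

    @property
    def n_frames(self) -> int:
        return len(self.distances)

    def valid(self) -> np.ndarray:
        return self.distances[np.isfinite(self.distances)]


@dataclass
class KsResult:
    D: float
    p_value: float
    n1: int
    n2: int
    stride: int


def interval_distance(track_a: Trajectory, track_b: Trajectory) -> IntervalSeries:
    """Per-frame distance between two center-of-mass trajectories."""
    if track_a.n_frames != track_b.n_frames:
        raise ValueError(
            f"trajectories differ in length: {track_a.n_frames} vs {track_b.n_frames}"
        )
    if track_a.fps != track_b.fps:
        raise ValueError("trajectories differ in fps")
    d = np.linalg.norm(track_a.positions - track_b.positions, axis=1)
    return IntervalSeries(distances=d, fps=track_a.fps)


def accumulation_curve(series: IntervalSeries, grid: np.ndarray) -> np.ndarray:
    """Empirical CDF of the interval distance on a grid: P(distance <= g).

    The boundary is closed, so a constant series at 5 cm evaluates to 1 at
    grid value 5.
    """
    valid = series.valid()
    if valid.size == 0:
        raise ValueError("all-missing interval series")
    grid = np.asarray(grid, dtype=float)
    sorted_d = np.sort(valid)
    return np.searchsorted(sorted_d, grid, side="right") / valid.size


def ks_compare(
    series_1: IntervalSeries,
    series_2: IntervalSeries,
    subsample_stride: int | None = None,
) -> KsResult:
    """Two-sample Kolmogorov-Smirnov comparison of two interval-distance series.

    ``subsample_stride`` (frames) decorrelates the frame-wise series before
    testing; the default is one second of frames.  The p-value is exact for
    small strided samples and asymptotic otherwise (scipy's automatic
    switch).
    """
    if subsample_stride is None:
        subsample_stride = max(int(round(series_1.fps)), 1)
    if subsample_stride < 1:
        raise ValueError("subsample_stride must be >= 1")
    s1 = series_1.distances[::subsample_stride]
    s2 = series_2.distances[::subsample_stride]
    s1 = s1[np.isfinite(s1)]
    s2 = s2[np.isfinite(s2)]
    if len(s1) < 10 or len(s2) < 10:
        raise ValueError(
            f"need >= 10 valid strided samples per series, got {len(s1)} and {len(s2)}"
        )
    res = stats.ks_2samp(s1, s2)
    return KsResult(
        D=float(res.statistic),
        p_value=float(res.pvalue),
        n1=len(s1),
        n2=len(s2),
        stride=subsample_stride,
    )


def correlation_length_frames(series: IntervalSeries, acf_cutoff: float = 0.1) -> int:
    """First lag at which the autocorrelation of the series drops below cutoff.

    Used to choose a subsampling stride at which strided frames are
    approximately independent.
    """
    x = series.valid()
    if x.size < 10:
        raise ValueError("series too short to estimate a correlation length")
    x = x - x.mean()
    var = float(np.dot(x, x))
    if var == 0:
        return 1
    max_lag = min(len(x) - 1, int(60 * series.fps))
    for lag in range(1, max_lag + 1):
        acf = float(np.dot(x[:-lag], x[lag:])) / var
        if abs(acf) < acf_cutoff:
            return lag
    return max_lag
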