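"""Trajectories, travel distance, and time-binned locomotion metrics.

The animal's position on a frame is the center of mass of its tracked body
parts — the unweighted mean of all non-missing keypoints.  Distances are
reported in cm (pixels are converted with the px/mm calibration at this
boundary) and times in seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .pose_io import PoseTrack


@dataclass
class Trajectory:
    """Per-frame center-of-mass positions in cm.

    ``positions`` has shape ``(n_frames, 2)`` with NaN rows where no keypoint
    was available; ``n_points`` records how many keypoints entered each mean.
    """

    positions: np.ndarray
    fps: float
    n_points: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (n_frames, 2)")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.n_points is None:
            self.n_points = np.where(self.valid_mask, 7, 0)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.positions).all(axis=1)


def center_of_mass(
    xy: np.ndarray, likelihood: np.ndarray | None = None,
    min_likelihood: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean of available keypoints per frame.

    Parameters
    ----------
    xy:
        ``(n_frames, k, 2)`` or a single frame ``(k, 2)``; NaN marks missing.
    likelihood, min_likelihood:
        Optionally exclude points below a confidence cutoff.  By default all
        non-missing points are included.

    Returns
    -------
    positions, n_points:
        Mean coordinates (NaN where no point was available — not an error)
        and the count of points used per frame.
    """
    xy = np.asarray(xy, dtype=float)
    squeeze = xy.ndim == 2
    if squeeze:
        xy = xy[None]
    use = np.isfinite(xy).all(axis=2)
    if likelihood is not None and min_likelihood is not None:
        lik = np.asarray(likelihood, dtype=float)
        if squeeze:
            lik = lik[None]
        use &= ~(lik < min_likelihood)
    n_points = use.sum(axis=1)
    masked = np.where(use[..., None], xy, 0.0)
    with np.errstate(invalid="ignore"):
        com = masked.sum(axis=1) / np.where(n_points > 0, n_points, np.nan)[:, None]
    if squeeze:
        return com[0], n_points[0]
    return com, n_points


def compute_trajectory(
    track: PoseTrack,
    px_per_mm: float | None = None,
    min_likelihood: float | None = None,
) -> Trajectory:
    """Center-of-mass trajectory of a track, converted from pixels to cm."""
    scale = px_per_mm if px_per_mm is not None else track.px_per_mm
    if scale is None or scale <= 0:
        raise ValueError("a positive px_per_mm calibration is required")
    com, n_points = center_of_mass(
        track.xy, track.likelihood, min_likelihood=min_likelihood
    )
    positions_cm = com / (scale * 10.0)  # px -> mm -> cm
    return Trajectory(positions=positions_cm, fps=track.fps, n_points=n_points)


def _window_slice(
    traj: Trajectory, window: tuple[float, float] | None, closed_end: bool = False
) -> slice:
    """Frame slice for a time window.

    Time metrics use half-open windows ``[start, end)`` so consecutive bins
    never double-count a frame.  Distance uses a closed end: the step from the
    last frame of one bin into the first frame of the next then belongs to the
    earlier bin, and per-bin distances sum exactly to the whole-track
    distance.
    """
    if window is None:
        return slice(0, traj.n_frames)
    start_s, end_s = window
    if end_s < start_s:
        raise ValueError(f"inverted window ({start_s}, {end_s})")
    start = int(np.ceil(start_s * traj.fps - 1e-9))
    if closed_end:
        stop = int(np.floor(end_s * traj.fps + 1e-9)) + 1
    else:
        stop = int(np.ceil(end_s * traj.fps - 1e-9))
    return slice(max(start, 0), min(max(stop, start), traj.n_frames))


def travel_distance(
    traj: Trajectory,
    window: tuple[float, float] | None = None,
    min_step_cm: float = 0.0,
    bridge_gaps_s: float = 0.0,
) -> float:
    """Sum of Euclidean step lengths between sequential valid frames, in cm.

    Steps spanning an invalid (missing-position) frame are skipped, never
    interpolated; setting ``bridge_gaps_s`` > 0 instead adds the straight-line
    distance across gaps no longer than that many seconds.  ``min_step_cm``
    discards steps below a displacement threshold — the standard device to
    keep tracker jitter on a near-stationary animal from accumulating into
    spurious distance (see the package methods note); the default 0.0 sums
    every step literally.
    """
    sl = _window_slice(traj, window, closed_end=True)
    pos = traj.positions[sl]
    if pos.shape[0] < 2:
        if window is not None and sl.stop - sl.start == 0:
            warnings.warn("empty window: no frames, distance is 0")
        return 0.0
    valid = np.isfinite(pos).all(axis=1)
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    pair_ok = valid[:-1] & valid[1:]
    use = pair_ok & (steps >= min_step_cm)
    total = float(steps[use].sum())
    if bridge_gaps_s > 0:
        total += _bridged_distance(pos, valid, traj.fps, bridge_gaps_s, min_step_cm)
    return total


def _bridged_distance(
    pos: np.ndarray, valid: np.ndarray, fps: float,
    bridge_gaps_s: float, min_step_cm: float,
) -> float:
    """Straight-line distance across missing gaps up to ``bridge_gaps_s``."""
    idx = np.flatnonzero(valid)
    if idx.size < 2:
        return 0.0
    total = 0.0
    gaps = np.diff(idx)
    max_gap = int(round(bridge_gaps_s * fps))
    for i in np.flatnonzero((gaps > 1) & (gaps <= max_gap + 1)):
        a, b = idx[i], idx[i + 1]
        d = float(np.linalg.norm(pos[b] - pos[a]))
        if d >= min_step_cm:
            total += d
    return total


def bin_metric(
    traj: Trajectory,
    bin_s: float,
    metric: str = "distance",
    arena=None,
    **metric_kwargs,
) -> list[dict]:
    """Evaluate a metric independently on consecutive ``bin_s`` windows.

    ``metric`` is ``"distance"`` (cm, via :func:`travel_distance`) or
    ``"center_time"`` (s; requires an open-field ``arena``).  The last partial
    bin is reported with its actual duration.  Returns a list of dicts with
    keys ``bin_start_s``, ``bin_end_s``, ``value``.
    """
    if bin_s <= 0:
        raise ValueError("bin_s must be positive")
    from .arenas import center_time  # local import to avoid a cycle

    out = []
    t = 0.0
    while t < traj.duration_s - 1e-9:
        end = min(t + bin_s, traj.duration_s)
        if metric == "distance":
            value = travel_distance(traj, window=(t, end), **metric_kwargs)
        elif metric == "center_time":
            if arena is None:
                raise ValueError("center_time binning requires an arena")
            value = center_time(traj, arena, window=(t, end))
        else:
            raise ValueError(f"unknown metric {metric!r}")
        out.append({"bin_start_s": t, "bin_end_s": end, "value": value})
        t += bin_s
    return out
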