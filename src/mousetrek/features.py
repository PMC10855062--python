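"""Per-frame pose features for supervised behavior classification.

The feature set covers the four families a SimBA-style pipeline computes from
calibrated keypoints — distances, movements, angles and areas:

* all pairwise keypoint distances (21 columns, cm),
* per-keypoint frame-to-frame movement (7 columns, cm),
* the body-axis angle at the body center (nose - body_center - tail_base,
  degrees),
* the convex-hull area of the seven points (cm^2),

plus rolling means and variances of each base feature over short windows
(0.2 s and 1 s by default, centered, truncated at the session edges).  For
two-animal sessions, inter-animal nose-nose and nose-tail_base distances and
the relative heading angle are appended.

Feature extraction is deterministic; frames where every keypoint is missing
are flagged invalid in the ``valid`` column rather than silently filled.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .pose_io import KEYPOINTS, KEYPOINT_INDEX, PoseTrack

DEFAULT_WINDOWS_S = (0.2, 1.0)


def _to_cm(track: PoseTrack, px_per_mm: float | None) -> np.ndarray:
    scale = px_per_mm if px_per_mm is not None else track.px_per_mm
    if scale is None or scale <= 0:
        raise ValueError("a positive px_per_mm calibration is required")
    return track.xy / (scale * 10.0)


def hull_area(points: np.ndarray) -> float:
    """Convex-hull area of a frame's available keypoints (cm^2).

    Fewer than three distinct points span no area; degenerate (collinear)
    configurations return 0.
    """
    pts = points[np.isfinite(points).all(axis=1)]
    if len(pts) < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # "volume" is area in 2-D
    except QhullError:
        return 0.0


def body_angle_deg(nose: np.ndarray, center: np.ndarray, tail: np.ndarray) -> np.ndarray:
    """Interior angle at the body center between the nose and tail vectors."""
    v1 = nose - center
    v2 = tail - center
    dot = (v1 * v2).sum(axis=-1)
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.clip(dot / (n1 * n2), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def heading_deg(track_xy_cm: np.ndarray) -> np.ndarray:
    """Body-axis heading (tail base to nose), degrees in (-180, 180]."""
    nose = track_xy_cm[:, KEYPOINT_INDEX["nose"], :]
    tail = track_xy_cm[:, KEYPOINT_INDEX["tail_base"], :]
    v = nose - tail
    return np.degrees(np.arctan2(v[:, 1], v[:, 0]))


def extract_features(
    tracks: PoseTrack | list[PoseTrack],
    px_per_mm: float | None = None,
    windows_s: tuple[float, ...] = DEFAULT_WINDOWS_S,
) -> pd.DataFrame:
    """Engineer the per-frame feature matrix for one or two animals.

    Returns a DataFrame with one row per frame, named feature columns, and a
    boolean ``valid`` column (False where an animal had no keypoint at all).
    """
    track_list = [tracks] if isinstance(tracks, PoseTrack) else list(tracks)
    if not 1 <= len(track_list) <= 2:
        raise ValueError("feature extraction supports one or two animals")
    n = track_list[0].n_frames
    fps = track_list[0].fps
    if any(t.n_frames != n for t in track_list):
        raise ValueError("tracks must have the same frame count")

    cols: dict[str, np.ndarray] = {}
    valid = np.ones(n, dtype=bool)
    xys = []
    for a, track in enumerate(track_list):
        prefix = f"a{a}_" if len(track_list) == 2 else ""
        xy = _to_cm(track, px_per_mm)
        xys.append(xy)
        valid &= ~track.missing_mask().all(axis=1)

        for i, j in combinations(range(len(KEYPOINTS)), 2):
            d = np.linalg.norm(xy[:, i, :] - xy[:, j, :], axis=1)
            cols[f"{prefix}dist_{KEYPOINTS[i]}_{KEYPOINTS[j]}"] = d
        for k, name in enumerate(KEYPOINTS):
            move = np.full(n, np.nan)
            step = np.linalg.norm(np.diff(xy[:, k, :], axis=0), axis=1)
            move[1:] = step
            move[0] = 0.0
            cols[f"{prefix}move_{name}"] = move
        cols[f"{prefix}body_angle_deg"] = body_angle_deg(
            xy[:, KEYPOINT_INDEX["nose"], :],
            xy[:, KEYPOINT_INDEX["body_center"], :],
            xy[:, KEYPOINT_INDEX["tail_base"], :],
        )
        cols[f"{prefix}hull_area"] = np.array([hull_area(xy[t]) for t in range(n)])

    if len(track_list) == 2:
        xy0, xy1 = xys
        nose0 = xy0[:, KEYPOINT_INDEX["nose"], :]
        nose1 = xy1[:, KEYPOINT_INDEX["nose"], :]
        tail1 = xy1[:, KEYPOINT_INDEX["tail_base"], :]
        tail0 = xy0[:, KEYPOINT_INDEX["tail_base"], :]
        cols["inter_nose_nose"] = np.linalg.norm(nose0 - nose1, axis=1)
        cols["inter_nose0_tail1"] = np.linalg.norm(nose0 - tail1, axis=1)
        cols["inter_nose1_tail0"] = np.linalg.norm(nose1 - tail0, axis=1)
        com0 = np.nanmean(xy0, axis=1)
        com1 = np.nanmean(xy1, axis=1)
        cols["inter_centroid"] = np.linalg.norm(com0 - com1, axis=1)
        h0 = heading_deg(xy0)
        h1 = heading_deg(xy1)
        rel = (h0 - h1 + 180.0) % 360.0 - 180.0
        cols["relative_heading_deg"] = rel
        # Heading of animal 0 relative to the bearing toward animal 1: small
        # values mean animal 0 points at its partner (a following signature).
        to_partner = np.degrees(
            np.arctan2(com1[:, 1] - com0[:, 1], com1[:, 0] - com0[:, 0])
        )
        cols["a0_heading_to_partner_deg"] = np.abs(
            (h0 - to_partner + 180.0) % 360.0 - 180.0
        )
        approach = np.full(n, np.nan)
        approach[1:] = -np.diff(cols["inter_centroid"])
        approach[0] = 0.0
        cols["inter_centroid_closing"] = approach

    base = pd.DataFrame(cols)
    frames = [base]
    for w in windows_s:
        span = max(int(round(w * fps)), 1)
        roll = base.rolling(window=span, center=True, min_periods=1)
        frames.append(roll.mean().add_suffix(f"_mean_{w}s"))
        frames.append(roll.var(ddof=0).add_suffix(f"_var_{w}s"))
    out = pd.concat(frames, axis=1)
    out["valid"] = valid
    return out


def feature_names(features: pd.DataFrame) -> list[str]:
    """Model-facing column names (everything except the validity flag)."""
    return [c for c in features.columns if c != "valid"]
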