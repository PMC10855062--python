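"""Reading and writing keypoint tables, annotations, and run configuration.

The on-disk dialect is the DeepLabCut 2.x CSV layout: a ``scorer`` header row,
an optional ``individuals`` row (multi-animal files), a ``bodyparts`` row, a
``coords`` row (``x``, ``y``, ``likelihood``), then one row per frame with the
frame index in the first column.  Seven canonical body parts are tracked per
animal: nose, left ear, right ear, body center, left flank, right flank and
tail base.  Missing detections are empty cells or NaN literals; both map to a
missing observation on read and are written back as empty cells.

Coordinates are kept in pixels at this layer; physical calibration (px/mm,
fps) travels in a sidecar :class:`RunConfig`, never inferred from the CSV.
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

#: Canonical body-part names, in fixed column order.
KEYPOINTS: tuple[str, ...] = (
    "nose",
    "left_ear",
    "right_ear",
    "body_center",
    "left_side",
    "right_side",
    "tail_base",
)

N_KEYPOINTS = len(KEYPOINTS)

#: Index of each canonical keypoint.
KEYPOINT_INDEX = {name: i for i, name in enumerate(KEYPOINTS)}


class PoseFormatError(ValueError):
    """Raised when a keypoint CSV does not match the expected layout."""


class AnnotationError(ValueError):
    """Raised when an annotation table violates its label contract."""


@dataclass
class PoseTrack:
    """Time-indexed keypoint observations for one animal.

    Parameters
    ----------
    animal_id:
        Identifier of the animal (``"animal0"`` for single-animal files).
    xy:
        Array of shape ``(n_frames, 7, 2)`` with x/y in pixels; NaN marks a
        missing observation (both coordinates NaN together).
    likelihood:
        Array of shape ``(n_frames, 7)`` with tracker confidence in [0, 1];
        NaN where the observation is missing.
    fps:
        Frames per second of the recording.
    px_per_mm:
        Spatial calibration; ``None`` until a config supplies it.
    """

    animal_id: str
    xy: np.ndarray
    likelihood: np.ndarray
    fps: float = 30.0
    px_per_mm: float | None = None

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        if self.xy.ndim != 3 or self.xy.shape[1:] != (N_KEYPOINTS, 2):
            raise ValueError(
                f"xy must have shape (n, {N_KEYPOINTS}, 2), got {self.xy.shape}"
            )
        if self.likelihood.shape != self.xy.shape[:2]:
            raise ValueError("likelihood shape must match xy frames x keypoints")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.px_per_mm is not None and self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be positive")
        finite = self.likelihood[np.isfinite(self.likelihood)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("likelihood values must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n_frames, 7)`` mask, True where the observation is missing."""
        return ~np.isfinite(self.xy).all(axis=2)

    def keypoint(self, name: str) -> np.ndarray:
        """Return the ``(n_frames, 2)`` coordinate series of one body part."""
        return self.xy[:, KEYPOINT_INDEX[name], :]

    def copy(self) -> "PoseTrack":
        return PoseTrack(
            animal_id=self.animal_id,
            xy=self.xy.copy(),
            likelihood=self.likelihood.copy(),
            fps=self.fps,
            px_per_mm=self.px_per_mm,
        )


@dataclass
class AnnotationTrack:
    """Per-frame behavior labels from a closed label set."""

    labels: np.ndarray
    label_set: tuple[str, ...]
    source: str = "human"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        bad = {l for l in self.labels if l not in self.label_set}
        if bad:
            raise AnnotationError(f"labels outside declared set: {sorted(bad)}")

    @property
    def n_frames(self) -> int:
        return len(self.labels)

    def binary(self, label: str) -> np.ndarray:
        """Boolean per-frame indicator for one behavior label."""
        return self.labels == label


@dataclass(frozen=True)
class RecordingSpec:
    """Recording metadata used to validate track lengths."""

    duration_s: float
    fps: float
    resolution: tuple[int, int] = (1920, 1080)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")


def expected_frame_count(spec: RecordingSpec) -> int:
    """Number of frames implied by a recording's duration and frame rate.

    A 10-minute recording at 30 fps yields 18,000 frames; lengths are rounded
    to the nearest whole frame.
    """
    if spec.duration_s < 0:
        raise ValueError("duration_s must be non-negative")
    return int(round(spec.duration_s * spec.fps))


@dataclass
class RunConfig:
    """Sidecar per-video configuration (geometry lives in :mod:`mousetrek.arenas`)."""

    fps: float = 30.0
    px_per_mm: float = 2.7
    arena_cm: tuple[float, float] = (40.0, 40.0)
    likelihood_threshold: float = 1.0
    extras: dict = field(default_factory=dict)


def load_config(path: str | os.PathLike) -> RunConfig:
    """Load a YAML run configuration; unknown keys are kept under ``extras``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)} - {"extras"}
    kwargs = {k: v for k, v in raw.items() if k in known}
    if "arena_cm" in kwargs:
        kwargs["arena_cm"] = tuple(kwargs["arena_cm"])
    extras = {k: v for k, v in raw.items() if k not in known}
    return RunConfig(**kwargs, extras=extras)


# ---------------------------------------------------------------------------
# DLC-dialect CSV reading / writing
# ---------------------------------------------------------------------------

def _check_header_row(cells: Sequence[str], expected_label: str, row_idx: int) -> None:
    if not cells or cells[0].strip() != expected_label:
        got = cells[0] if cells else "<empty>"
        raise PoseFormatError(
            f"header row {row_idx}: expected leading cell {expected_label!r}, "
            f"got {got!r}"
        )


def read_pose_csv(
    path: str | os.PathLike,
    dialect: str = "single",
    strict_bodyparts: bool = True,
) -> list[PoseTrack]:
    """Read a DeepLabCut-dialect keypoint CSV into one PoseTrack per animal.

    Parameters
    ----------
    dialect:
        ``"single"`` for the 3-header layout (scorer/bodyparts/coords) or
        ``"multi"`` for the 4-header multi-animal layout with an
        ``individuals`` row.
    strict_bodyparts:
        When True (default) the file must contain exactly the seven canonical
        body parts per animal; set False to accept any body-part set that is a
        superset ordering of the canonical seven.
    """
    if dialect not in ("single", "multi"):
        raise ValueError(f"unknown dialect {dialect!r}")
    n_header = 3 if dialect == "single" else 4
    with open(path) as fh:
        header_lines = [fh.readline() for _ in range(n_header)]
    if any(line == "" for line in header_lines):
        n_found = sum(1 for line in header_lines if line)
        raise PoseFormatError(
            f"file has {n_found} rows; a {dialect}-dialect file needs at least "
            f"{n_header} header rows"
        )
    rows = [line.rstrip("\n").rstrip("\r").split(",") for line in header_lines]
    _check_header_row(rows[0], "scorer", 0)
    if dialect == "multi":
        _check_header_row(rows[1], "individuals", 1)
        individuals_row = rows[1][1:]
        bp_row_idx = 2
    else:
        individuals_row = None
        bp_row_idx = 1
    _check_header_row(rows[bp_row_idx], "bodyparts", bp_row_idx)
    _check_header_row(rows[bp_row_idx + 1], "coords", bp_row_idx + 1)

    bodyparts = [c.strip() for c in rows[bp_row_idx][1:]]
    coords = [c.strip() for c in rows[bp_row_idx + 1][1:]]
    n_cols = len(bodyparts)

    if individuals_row is None:
        individuals = ["animal0"] * n_cols
    else:
        individuals = [c.strip() for c in individuals_row]

    # Group columns by animal, preserving file order of first appearance.
    animal_order: list[str] = []
    for ind in individuals:
        if ind not in animal_order:
            animal_order.append(ind)

    try:
        data = pd.read_csv(
            path, skiprows=n_header, header=None, float_precision="round_trip"
        )
    except pd.errors.EmptyDataError:
        data = pd.DataFrame(np.empty((0, n_cols + 1)))
    n_frames = len(data)

    tracks: list[PoseTrack] = []
    for animal in animal_order:
        cols = [j for j in range(n_cols) if individuals[j] == animal]
        seen: dict[str, dict[str, int]] = {}
        for j in cols:
            seen.setdefault(bodyparts[j], {})[coords[j]] = j
        unknown = [bp for bp in seen if bp not in KEYPOINT_INDEX]
        if unknown and strict_bodyparts:
            raise PoseFormatError(
                f"unknown body part(s) {unknown} for animal {animal!r}; "
                f"expected {list(KEYPOINTS)}"
            )
        missing_bp = [bp for bp in KEYPOINTS if bp not in seen]
        if missing_bp:
            raise PoseFormatError(
                f"animal {animal!r} lacks body part(s) {missing_bp}; "
                f"expected {list(KEYPOINTS)}"
            )
        xy = np.full((n_frames, N_KEYPOINTS, 2), np.nan)
        lik = np.full((n_frames, N_KEYPOINTS), np.nan)
        for k, bp in enumerate(KEYPOINTS):
            for axis, coord in enumerate(("x", "y")):
                if coord not in seen[bp]:
                    raise PoseFormatError(
                        f"body part {bp!r} of animal {animal!r} lacks a "
                        f"{coord!r} column"
                    )
                xy[:, k, axis] = _numeric_column(data, seen[bp][coord] + 1, bp, coord)
            if "likelihood" in seen[bp]:
                lik[:, k] = _numeric_column(
                    data, seen[bp]["likelihood"] + 1, bp, "likelihood"
                )
        # A half-missing pair (x without y) counts as missing.
        half = np.isnan(xy).any(axis=2)
        xy[half] = np.nan
        lik[half] = np.nan
        tracks.append(PoseTrack(animal_id=animal, xy=xy, likelihood=lik))
    return tracks


def _numeric_column(data: pd.DataFrame, col: int, bp: str, coord: str) -> np.ndarray:
    vals = data.iloc[:, col]
    if vals.dtype.kind in "fiu":
        return vals.to_numpy(dtype=float)
    out = pd.to_numeric(vals, errors="coerce")
    bad = out.isna() & vals.notna()
    if bad.any():
        frame = int(np.flatnonzero(bad.to_numpy())[0])
        raise PoseFormatError(
            f"non-numeric value {vals.iloc[frame]!r} at frame {frame}, "
            f"column ({bp}, {coord})"
        )
    return out.to_numpy(dtype=float)


def write_pose_csv(
    tracks: PoseTrack | Sequence[PoseTrack],
    path: str | os.PathLike,
    scorer: str = "mousetrek",
) -> None:
    """Write one or more PoseTracks in the DLC CSV dialect.

    A single track is written in the 3-header single-animal layout; a sequence
    of tracks in the 4-header multi-animal layout.  Missing observations
    become empty cells, so a read/write round trip preserves missingness.
    """
    single = isinstance(tracks, PoseTrack)
    track_list = [tracks] if single else list(tracks)
    if not track_list:
        raise ValueError("no tracks to write")
    n_frames = track_list[0].n_frames
    if any(t.n_frames != n_frames for t in track_list):
        raise ValueError("all tracks must have the same frame count")

    header_rows: list[list[str]] = []
    n_cols = len(track_list) * N_KEYPOINTS * 3
    header_rows.append(["scorer"] + [scorer] * n_cols)
    if not single:
        ind_row = ["individuals"]
        for t in track_list:
            ind_row += [t.animal_id] * (N_KEYPOINTS * 3)
        header_rows.append(ind_row)
    bp_row = ["bodyparts"]
    coord_row = ["coords"]
    for _t in track_list:
        for bp in KEYPOINTS:
            bp_row += [bp] * 3
            coord_row += ["x", "y", "likelihood"]
    header_rows += [bp_row, coord_row]

    cols = []
    for t in track_list:
        for k in range(N_KEYPOINTS):
            cols.append(t.xy[:, k, 0])
            cols.append(t.xy[:, k, 1])
            cols.append(t.likelihood[:, k])
    body = pd.DataFrame(np.column_stack(cols))
    body.insert(0, "frame", np.arange(n_frames))

    buf = io.StringIO()
    for row in header_rows:
        buf.write(",".join(row) + "\n")
    # %.17g guarantees bit-exact float round trips through the text format
    body.to_csv(buf, header=False, index=False, na_rep="", float_format="%.17g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def read_annotations(
    path: str | os.PathLike,
    label_set: Iterable[str],
    n_frames: int,
    source: str = "human",
) -> AnnotationTrack:
    """Read a sparse (frame, label) CSV into a dense per-frame track.

    Frames not listed in the file are labeled ``"none"``.  The file may have a
    ``frame,label`` header or be headerless.
    """
    label_set = tuple(label_set)
    if "none" not in label_set:
        label_set = ("none",) + label_set
    labels = np.full(n_frames, "none", dtype=object)
    try:
        raw = pd.read_csv(path, header=None, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return AnnotationTrack(labels=labels, label_set=label_set, source=source)
    if len(raw) and raw.iloc[0, 0].strip().lower() == "frame":
        raw = raw.iloc[1:]
    for _, row in raw.iterrows():
        frame = int(row.iloc[0])
        label = str(row.iloc[1]).strip()
        if label not in label_set:
            raise AnnotationError(
                f"label {label!r} at frame {frame} not in declared set "
                f"{sorted(label_set)}"
            )
        if not 0 <= frame < n_frames:
            raise AnnotationError(f"frame {frame} outside track of {n_frames} frames")
        labels[frame] = label
    return AnnotationTrack(labels=labels, label_set=label_set, source=source)


def write_annotations(track: AnnotationTrack, path: str | os.PathLike) -> None:
    """Write only the non-``none`` frames as a sparse (frame, label) CSV."""
    idx = np.flatnonzero(track.labels != "none")
    pd.DataFrame({"frame": idx, "label": track.labels[idx]}).to_csv(path, index=False)
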