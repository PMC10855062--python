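"""Arena geometry and test scoring: open field, cliff avoidance, Y-maze.

Three standard assays are scored from a center-of-mass trajectory:

* **Open field** — a 40 x 40 cm box; time spent in the inner 20 x 20 cm
  center zone (10 cm in from every wall) indexes anxiety inversely.
* **Cliff avoidance reaction (CAR)** — a 12.5 cm circular platform in the
  arena center; the latency to the first jump off and the number of jumps
  index impulsivity.  An animal that never jumps is censored at the test
  duration (900 s).
* **Y-maze** — three 35 x 6 cm arms at 120 degrees; spontaneous alternation
  (entering the arm not visited in the previous two entries) indexes working
  memory.

Zone membership uses a closed boundary: a position exactly on a zone edge
counts as inside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .kinematics import Trajectory, _window_slice


@dataclass
class ArenaConfig:
    """Physical geometry of a behavioral test, in cm."""

    kind: str  # "open_field" | "car" | "ymaze"
    bounds: tuple[float, float, float, float] = (0.0, 0.0, 40.0, 40.0)
    center_zone: tuple[float, float, float, float] | None = None
    platform_center: tuple[float, float] | None = None
    platform_diameter_cm: float | None = None
    arm_length_cm: float = 35.0
    arm_width_cm: float = 6.0
    arm_angles_deg: tuple[float, ...] = (90.0, 210.0, 330.0)
    arm_origin: tuple[float, float] = (0.0, 0.0)
    test_duration_s: float = 900.0

    def __post_init__(self) -> None:
        if self.test_duration_s <= 0:
            raise ValueError("test_duration_s must be positive")
        x0, y0, x1, y1 = self.bounds
        if x1 <= x0 or y1 <= y0:
            raise ValueError("degenerate arena bounds")
        if self.center_zone is not None:
            cx0, cy0, cx1, cy1 = self.center_zone
            if not (x0 < cx0 < cx1 < x1 and y0 < cy0 < cy1 < y1):
                raise ValueError("center_zone must lie strictly inside bounds")
        if self.platform_center is not None:
            px, py = self.platform_center
            r = (self.platform_diameter_cm or 0.0) / 2.0
            if not (x0 <= px - r and px + r <= x1 and y0 <= py - r and py + r <= y1):
                raise ValueError("platform must lie inside bounds")

    def arm_directions(self) -> np.ndarray:
        ang = np.deg2rad(np.asarray(self.arm_angles_deg))
        return np.column_stack([np.cos(ang), np.sin(ang)])


def open_field_arena(
    width_cm: float = 40.0, height_cm: float = 40.0, center_inset_cm: float = 10.0,
    test_duration_s: float = 1800.0,
) -> ArenaConfig:
    """Standard open field: 40 x 40 cm with a 20 x 20 cm center zone."""
    return ArenaConfig(
        kind="open_field",
        bounds=(0.0, 0.0, width_cm, height_cm),
        center_zone=(
            center_inset_cm,
            center_inset_cm,
            width_cm - center_inset_cm,
            height_cm - center_inset_cm,
        ),
        test_duration_s=test_duration_s,
    )


def car_arena(
    width_cm: float = 40.0, height_cm: float = 40.0,
    platform_diameter_cm: float = 12.5, test_duration_s: float = 900.0,
) -> ArenaConfig:
    """Cliff-avoidance arena: central 12.5 cm platform, 15-minute test."""
    return ArenaConfig(
        kind="car",
        bounds=(0.0, 0.0, width_cm, height_cm),
        platform_center=(width_cm / 2.0, height_cm / 2.0),
        platform_diameter_cm=platform_diameter_cm,
        test_duration_s=test_duration_s,
    )


def ymaze_arena(
    arm_length_cm: float = 35.0, arm_width_cm: float = 6.0,
    test_duration_s: float = 480.0,
) -> ArenaConfig:
    """Y-maze with three arms at 120 degrees radiating from the origin."""
    L = arm_length_cm
    return ArenaConfig(
        kind="ymaze",
        bounds=(-L - 5.0, -L - 5.0, L + 5.0, L + 5.0),
        arm_length_cm=arm_length_cm,
        arm_width_cm=arm_width_cm,
        test_duration_s=test_duration_s,
    )


@dataclass
class CarResult:
    latency_first_jump_s: float
    n_jumps: int
    censored: bool


@dataclass
class YmazeResult:
    entry_sequence: list[int]
    n_entries: int
    n_alternations: int
    alternation_pct: float | None
    alternation_pct_conventional: float | None = None


# ---------------------------------------------------------------------------
# Open field
# ---------------------------------------------------------------------------

def in_zone(positions: np.ndarray, zone: tuple[float, float, float, float]) -> np.ndarray:
    """Closed-boundary rectangle membership for ``(n, 2)`` positions."""
    x0, y0, x1, y1 = zone
    p = np.asarray(positions, dtype=float)
    return (
        (p[:, 0] >= x0) & (p[:, 0] <= x1) & (p[:, 1] >= y0) & (p[:, 1] <= y1)
    )


def center_time(
    traj: Trajectory, arena: ArenaConfig, window: tuple[float, float] | None = None
) -> float:
    """Seconds spent inside the open-field center zone (valid frames / fps)."""
    if arena.kind != "open_field":
        raise ValueError("center_time requires an open-field arena")
    if arena.center_zone is None:
        raise ValueError("arena has no center zone defined")
    sl = _window_slice(traj, window)
    pos = traj.positions[sl]
    valid = np.isfinite(pos).all(axis=1)
    if valid.sum() == 0:
        warnings.warn("trajectory entirely invalid in window; center time undefined")
        return float("nan")
    inside = in_zone(pos[valid], arena.center_zone)
    return float(inside.sum() / traj.fps)


def edge_time(
    traj: Trajectory, arena: ArenaConfig, window: tuple[float, float] | None = None
) -> float:
    """Valid time in the window not spent in the center zone."""
    sl = _window_slice(traj, window)
    valid = np.isfinite(traj.positions[sl]).all(axis=1)
    ct = center_time(traj, arena, window)
    return float(valid.sum() / traj.fps) - ct


# ---------------------------------------------------------------------------
# Cliff avoidance reaction
# ---------------------------------------------------------------------------

def score_car(
    traj: Trajectory, arena: ArenaConfig, min_off_s: float = 0.5
) -> CarResult:
    """Latency to the first jump off the platform and the jump count.

    A jump is an on-platform to off-platform transition whose off period
    lasts at least ``min_off_s`` (transients shorter than that are treated as
    tracking flicker).  After a jump the animal is returned to the platform by
    the experimenter, so each subsequent qualifying off period after an
    on-platform re-entry counts as another jump.  With no jump, the latency is
    censored at the test duration (900 s by default) and the count is 0.
    """
    if arena.kind != "car":
        raise ValueError("score_car requires a CAR arena")
    if arena.platform_center is None or arena.platform_diameter_cm is None:
        raise ValueError("arena has no platform defined")
    center = np.asarray(arena.platform_center)
    radius = arena.platform_diameter_cm / 2.0
    valid = traj.valid_mask
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        raise ValueError("trajectory has no valid frames")
    on = np.linalg.norm(traj.positions[idx] - center, axis=1) <= radius
    if not on[0]:
        warnings.warn(
            "trajectory does not start on the platform; scoring from first "
            "on-platform frame"
        )
        first_on = np.argmax(on) if on.any() else None
        if first_on is None:
            raise ValueError("animal never on the platform; cannot score CAR")
        idx, on = idx[first_on:], on[first_on:]

    min_off_frames = max(int(round(min_off_s * traj.fps)), 1)
    n_jumps = 0
    latency = None
    i = 0
    n = len(on)
    while i < n:
        if not on[i]:
            run_start = i
            while i < n and not on[i]:
                i += 1
            if (i - run_start) >= min_off_frames:
                n_jumps += 1
                if latency is None:
                    latency = idx[run_start] / traj.fps
        else:
            i += 1
    if latency is None:
        return CarResult(
            latency_first_jump_s=float(arena.test_duration_s), n_jumps=0, censored=True
        )
    return CarResult(latency_first_jump_s=float(latency), n_jumps=n_jumps, censored=False)


# ---------------------------------------------------------------------------
# Y-maze
# ---------------------------------------------------------------------------

def arm_entry_sequence(
    traj: Trajectory,
    arena: ArenaConfig,
    entry_fraction: float = 0.3,
    junction_radius_cm: float | None = None,
) -> list[int]:
    """Ordered arm indices entered, one per distal-region visit.

    An entry registers when the position passes ``entry_fraction`` of the arm
    length from the junction; the visit ends once the animal leaves that arm
    (back into the junction or another arm), after which the same arm can be
    re-entered.  All four limbs are invisible to a keypoint tracker, so the
    distal-fraction rule on the body position is the documented proxy for the
    conventional four-limb entry criterion.
    """
    if arena.kind != "ymaze":
        raise ValueError("arm_entry_sequence requires a Y-maze arena")
    dirs = arena.arm_directions()
    origin = np.asarray(arena.arm_origin)
    half_w = arena.arm_width_cm / 2.0
    threshold = entry_fraction * arena.arm_length_cm
    # Inside this radius the arms are not distinguishable: the junction.
    r_junction = (
        junction_radius_cm if junction_radius_cm is not None else arena.arm_width_cm
    )

    entries: list[int] = []
    active: int | None = None
    for p in traj.positions:
        if not np.isfinite(p).all():
            continue
        rel = p - origin
        proj = dirs @ rel
        perp = np.abs(rel[0] * dirs[:, 1] - rel[1] * dirs[:, 0])
        in_arm = (proj >= 0) & (proj <= arena.arm_length_cm) & (perp <= half_w)
        if float(np.hypot(rel[0], rel[1])) <= r_junction or not in_arm.any():
            arm = None
        else:
            arm = int(np.argmax(np.where(in_arm, proj, -np.inf)))
        if active is not None and arm != active:
            active = None
        if active is None and arm is not None and proj[arm] >= threshold:
            entries.append(arm)
            active = arm
    return entries


def count_alternations(entries: list[int]) -> int:
    """Entries (from the third on) differing from both of the previous two."""
    return sum(
        1
        for i in range(2, len(entries))
        if entries[i] != entries[i - 1] and entries[i] != entries[i - 2]
    )


def score_entry_sequence(entries: list[int]) -> YmazeResult:
    """Alternation scores for an entry sequence.

    ``alternation_pct`` divides by the total number of entries (the
    formulation used in the source protocol); the conventional denominator
    (entries - 2), under which perfect alternation scores 100%, is reported
    alongside.
    """
    n = len(entries)
    n_alt = count_alternations(entries)
    pct = 100.0 * n_alt / n if n >= 3 else None
    pct_conv = 100.0 * n_alt / (n - 2) if n >= 3 else None
    return YmazeResult(
        entry_sequence=list(entries),
        n_entries=n,
        n_alternations=n_alt,
        alternation_pct=pct,
        alternation_pct_conventional=pct_conv,
    )


def score_ymaze(
    traj: Trajectory, arena: ArenaConfig, entry_fraction: float = 0.3
) -> YmazeResult:
    """Arm entries and spontaneous alternation from a Y-maze trajectory."""
    return score_entry_sequence(arm_entry_sequence(traj, arena, entry_fraction))
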