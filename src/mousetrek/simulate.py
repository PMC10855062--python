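"""Synthetic behavior sessions with known ground truth.

The generator emulates the recording regime of the real assays — a
40 x 40 cm arena filmed at 30 fps for 10-30 minutes, one or two C57BL/6J-like
animals — so that every pipeline stage can be tested against exact ground
truth without any recorded data.

**Latent model.**  Each animal follows a semi-Markov behavior schedule over
the states locomote / rest / groom / rear (plus follow / sniff for the
subject of a two-animal session), with geometric dwell times.  Movement is
waypoint-based: during locomotion the animal travels in straight segments at
10-16 cm/s toward waypoints sampled inside the arena, drawn from the center
zone with a preset-specific probability — the knob through which the control
and PNE-like presets encode center avoidance.  Waypoints keep a margin from
the walls, so the body never leaves the arena (the arena is convex).
Following steers the subject toward the juvenile's current position,
re-aimed every half second, stopping short of contact; sniffing holds the
subject at body contact, its nose within ~2 cm of the juvenile.  A sniff
scheduled while the animals are far apart is executed as a follow instead
(ground-truth annotations always describe the executed behavior).

**Observation model.**  Seven keypoints per animal are emitted from a rigid
zero-mean template rotated to the heading and deformed by state (rearing
contracts the body axis, grooming hunches it and oscillates the nose), then
degraded: Gaussian jitter (default sigma 0.1 cm per keypoint), occasional
low-likelihood frames, random dropout (missing points), and optional
single-frame teleport artifacts whose frame/keypoint log is returned as
ground truth for outlier-correction benchmarks.

All randomness derives from one seed via independent child streams per
animal and per noise channel, so enabling a noise channel never perturbs the
latent trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .arenas import ArenaConfig, car_arena, open_field_arena, ymaze_arena
from .behavior import BoutTable, bouts_from_binary
from .kinematics import Trajectory
from .pose_io import KEYPOINTS, KEYPOINT_INDEX, AnnotationTrack, PoseTrack
from .social import IntervalSeries
from .stereology import StereologyCounts

# Zero-mean body template in cm, heading along +x (nose first).
_RAW_TEMPLATE = np.array(
    [
        [3.2, 0.0],    # nose
        [2.3, 0.9],    # left_ear
        [2.3, -0.9],   # right_ear
        [0.0, 0.0],    # body_center
        [0.0, 1.3],    # left_side
        [0.0, -1.3],   # right_side
        [-3.4, 0.0],   # tail_base
    ]
)
TEMPLATE = _RAW_TEMPLATE - _RAW_TEMPLATE.mean(axis=0)

STATE_TO_LABEL = {
    "groom": "grooming",
    "rear": "rearing",
    "follow": "following",
    "sniff": "sniffing",
}

SINGLE_LABELS = ("none", "grooming", "rearing")
SOCIAL_LABELS = ("none", "grooming", "rearing", "following", "sniffing")


@dataclass
class BehaviorParams:
    """Markov behavior schedule and kinematics for one animal."""

    dwell_s: dict[str, float]
    trans: dict[str, dict[str, float]]
    speed_range_cm_s: tuple[float, float] = (10.0, 16.0)
    center_waypoint_prob: float = 0.35
    wall_margin_cm: float = 4.0
    follow_speed_cm_s: float = 14.0
    follow_stop_cm: float = 4.0
    sniff_radius_cm: float = 3.0
    sniff_gate_cm: float = 8.0
    body_scale: float = 1.0

    def __post_init__(self) -> None:
        for state, row in self.trans.items():
            total = sum(row.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"transition row {state!r} sums to {total}, not 1")
            if any(p < 0 or p > 1 for p in row.values()):
                raise ValueError("transition probabilities must lie in [0, 1]")
        if any(d <= 0 for d in self.dwell_s.values()):
            raise ValueError("dwell means must be positive")


@dataclass
class ObservationParams:
    """Keypoint degradation applied on top of the latent pose."""

    jitter_cm: float = 0.1
    lowlik_prob: float = 0.02
    dropout_prob: float = 0.005
    teleport_rate: float = 0.0
    teleport_min_jump_cm: float = 15.0
    px_per_mm: float = 2.7


@dataclass
class SyntheticScenario:
    seed: int
    arena: ArenaConfig
    n_animals: int = 1
    duration_s: float = 600.0
    fps: float = 30.0
    behavior: BehaviorParams | None = None
    juvenile_behavior: BehaviorParams | None = None
    obs: ObservationParams = field(default_factory=ObservationParams)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass
class SessionData:
    """Generated session: observed tracks plus exact latent ground truth."""

    tracks: list[PoseTrack]
    annotations: list[AnnotationTrack]
    arena: ArenaConfig
    fps: float
    latent_positions: list[np.ndarray]
    states: list[np.ndarray]
    artifacts: list[list[tuple[int, str]]]
    px_per_mm: float
    extras: dict = field(default_factory=dict)

    def true_trajectory(self, animal: int = 0) -> Trajectory:
        return Trajectory(positions=self.latent_positions[animal].copy(), fps=self.fps)

    def true_interval_series(self) -> IntervalSeries:
        if len(self.latent_positions) < 2:
            raise ValueError("interval series needs a two-animal session")
        d = np.linalg.norm(
            self.latent_positions[0] - self.latent_positions[1], axis=1
        )
        return IntervalSeries(distances=d, fps=self.fps)

    def true_bouts(self, animal: int, label: str) -> BoutTable:
        state = {v: k for k, v in STATE_TO_LABEL.items()}[label]
        return bouts_from_binary(
            self.states[animal] == state, fps=self.fps, label=label
        )


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _single_behavior(groom_scale: float, rear_scale: float,
                     center_prob: float) -> BehaviorParams:
    def row(**probs: float) -> dict[str, float]:
        total = sum(probs.values())
        return {k: v / total for k, v in probs.items()}

    return BehaviorParams(
        dwell_s={"locomote": 5.0, "rest": 4.0, "groom": 8.0, "rear": 2.0},
        trans={
            "locomote": row(rest=0.5, groom=0.3 * groom_scale, rear=0.2 * rear_scale),
            "rest": row(locomote=0.6, groom=0.25 * groom_scale, rear=0.15 * rear_scale),
            "groom": row(locomote=0.5, rest=0.3, rear=0.2 * rear_scale),
            "rear": row(locomote=0.7, rest=0.2, groom=0.1 * groom_scale),
        },
        center_waypoint_prob=center_prob,
    )


def _subject_behavior(groom_scale: float, rear_scale: float, social_scale: float,
                      center_prob: float) -> BehaviorParams:
    def row(**probs: float) -> dict[str, float]:
        total = sum(probs.values())
        return {k: v / total for k, v in probs.items()}

    g, r, s = groom_scale, rear_scale, social_scale
    return BehaviorParams(
        dwell_s={
            "locomote": 4.0, "rest": 3.0, "groom": 6.0, "rear": 2.0,
            "follow": 3.0, "sniff": 2.5,
        },
        trans={
            "locomote": row(rest=0.30, groom=0.10 * g, rear=0.10 * r,
                            follow=0.30 * s, sniff=0.20 * s),
            "rest": row(locomote=0.45, groom=0.10 * g, rear=0.05 * r,
                        follow=0.25 * s, sniff=0.15 * s),
            "groom": row(locomote=0.55, rest=0.25, follow=0.20 * s),
            "rear": row(locomote=0.60, rest=0.20, follow=0.20 * s),
            "follow": row(sniff=0.55 * s, locomote=0.30, rest=0.15),
            "sniff": row(follow=0.35 * s, locomote=0.40, rest=0.25),
        },
        center_waypoint_prob=center_prob,
    )


def _juvenile_behavior() -> BehaviorParams:
    return BehaviorParams(
        dwell_s={"locomote": 5.0, "rest": 3.0, "rear": 2.0},
        trans={
            "locomote": {"rest": 0.7, "rear": 0.3},
            "rest": {"locomote": 0.85, "rear": 0.15},
            "rear": {"locomote": 0.7, "rest": 0.3},
        },
        center_waypoint_prob=0.3,
        body_scale=0.75,
    )


@dataclass(frozen=True)
class Preset:
    """Group-level parameter bundle; control vs PNE-like differ only in the
    effect-direction knobs (center preference, social/groom/rear initiation,
    platform-exit hazard, alternation bias)."""

    name: str
    center_waypoint_prob: float
    groom_scale: float
    rear_scale: float
    social_scale: float
    car_exit_hazard_per_s: float
    ymaze_p_alternate: float


PRESETS = {
    "control": Preset(
        name="control",
        center_waypoint_prob=0.35,
        groom_scale=1.0,
        rear_scale=1.0,
        social_scale=1.0,
        car_exit_hazard_per_s=0.0008,
        ymaze_p_alternate=0.75,
    ),
    "pne": Preset(
        name="pne",
        center_waypoint_prob=0.12,
        groom_scale=0.5,
        rear_scale=0.6,
        social_scale=0.5,
        car_exit_hazard_per_s=0.006,
        ymaze_p_alternate=0.55,
    ),
}


def make_scenario(
    preset: str | Preset = "control",
    seed: int = 0,
    n_animals: int = 1,
    duration_s: float | None = None,
    fps: float = 30.0,
    obs: ObservationParams | None = None,
) -> SyntheticScenario:
    """Scenario for a preset: 30-min open field (one animal) or 10-min
    juvenile interaction (two animals)."""
    p = PRESETS[preset] if isinstance(preset, str) else preset
    if duration_s is None:
        duration_s = 1800.0 if n_animals == 1 else 600.0
    if n_animals == 1:
        behavior = _single_behavior(p.groom_scale, p.rear_scale, p.center_waypoint_prob)
        juvenile = None
    else:
        behavior = _subject_behavior(
            p.groom_scale, p.rear_scale, p.social_scale, p.center_waypoint_prob
        )
        juvenile = _juvenile_behavior()
    return SyntheticScenario(
        seed=seed,
        arena=open_field_arena(),
        n_animals=n_animals,
        duration_s=duration_s,
        fps=fps,
        behavior=behavior,
        juvenile_behavior=juvenile,
        obs=obs or ObservationParams(),
    )


# ---------------------------------------------------------------------------
# Latent simulation
# ---------------------------------------------------------------------------

def _sample_segments(rng, params: BehaviorParams, n_frames: int, fps: float):
    segs: list[tuple[str, int]] = []
    total = 0
    state = "locomote" if "locomote" in params.dwell_s else next(iter(params.dwell_s))
    while total < n_frames:
        mean_frames = max(params.dwell_s[state] * fps, 1.0)
        dur = int(rng.geometric(1.0 / mean_frames))
        dur = max(min(dur, n_frames - total), 1)
        segs.append((state, dur))
        total += dur
        nxt = list(params.trans[state].keys())
        probs = np.array([params.trans[state][s] for s in nxt])
        state = nxt[rng.choice(len(nxt), p=probs / probs.sum())]
    return segs


def _sample_waypoint(rng, params: BehaviorParams, arena: ArenaConfig) -> np.ndarray:
    x0, y0, x1, y1 = arena.bounds
    m = params.wall_margin_cm
    if arena.center_zone is not None and rng.random() < params.center_waypoint_prob:
        cx0, cy0, cx1, cy1 = arena.center_zone
        return rng.uniform([cx0 + 1, cy0 + 1], [cx1 - 1, cy1 - 1])
    # wall-biased: uniform over the arena interior excluding the center zone
    for _ in range(64):
        p = rng.uniform([x0 + m, y0 + m], [x1 - m, y1 - m])
        if arena.center_zone is None:
            return p
        cx0, cy0, cx1, cy1 = arena.center_zone
        if not (cx0 <= p[0] <= cx1 and cy0 <= p[1] <= cy1):
            return p
    return p


def _fill_locomotion(rng, params, arena, pos, start, dur, p, fps):
    j = start
    remaining = dur
    while remaining > 0:
        w = _sample_waypoint(rng, params, arena)
        v = rng.uniform(*params.speed_range_cm_s)
        step = v / fps
        d = float(np.linalg.norm(w - p))
        if d < 1e-9:
            pos[j] = p
            j += 1
            remaining -= 1
            continue
        n_steps = int(np.ceil(d / step))
        k = min(n_steps, remaining)
        frac = np.minimum(np.arange(1, k + 1) * step / d, 1.0)
        pos[j : j + k] = p + frac[:, None] * (w - p)
        p = pos[j + k - 1].copy()
        j += k
        remaining -= k
    return p


def _fill_follow(rng, params, pos, start, dur, p, fps, partner_pos):
    j = start
    remaining = dur
    step = params.follow_speed_cm_s / fps
    while remaining > 0:
        k = min(int(round(fps / 2)) or 1, remaining)
        tgt = partner_pos[j]
        d = float(np.linalg.norm(tgt - p))
        avail = max(d - params.follow_stop_cm, 0.0)
        n_move = min(k, int(avail / step))
        if n_move > 0 and d > 1e-9:
            u = (tgt - p) / d
            pos[j : j + n_move] = p + np.outer(
                np.arange(1, n_move + 1) * step, u
            )
            p = pos[j + n_move - 1].copy()
        if n_move < k:
            pos[j + n_move : j + k] = p
        j += k
        remaining -= k
    return p


def _fill_sniff(rng, params, pos, start, dur, p, fps, partner_pos):
    angles = np.cumsum(rng.normal(0.0, 0.1, dur))
    base = np.arctan2(p[1] - partner_pos[start][1], p[0] - partner_pos[start][0])
    theta = base + angles
    offset = params.sniff_radius_cm * np.column_stack([np.cos(theta), np.sin(theta)])
    pos[start : start + dur] = partner_pos[start : start + dur] + offset
    return pos[start + dur - 1].copy()


def _latent_track(
    rng, params: BehaviorParams, arena: ArenaConfig, n_frames: int, fps: float,
    start_pos: np.ndarray, partner_pos: np.ndarray | None = None,
):
    segs = _sample_segments(rng, params, n_frames, fps)
    pos = np.empty((n_frames, 2))
    states = np.empty(n_frames, dtype=object)
    p = np.asarray(start_pos, dtype=float).copy()
    i = 0
    for state, dur in segs:
        if state == "sniff" and partner_pos is not None:
            d = float(np.linalg.norm(partner_pos[i] - p))
            if d > params.sniff_gate_cm:
                state = "follow"  # too far for contact; executed as pursuit
        states[i : i + dur] = state
        if state == "locomote":
            p = _fill_locomotion(rng, params, arena, pos, i, dur, p, fps)
        elif state == "follow":
            if partner_pos is None:
                raise ValueError("follow state requires a partner track")
            p = _fill_follow(rng, params, pos, i, dur, p, fps, partner_pos)
        elif state == "sniff":
            p = _fill_sniff(rng, params, pos, i, dur, p, fps, partner_pos)
        else:  # rest / groom / rear: stationary body
            pos[i : i + dur] = p
        i += dur
    # keep inside the arena with a small body margin (sniff offsets can poke out)
    x0, y0, x1, y1 = arena.bounds
    np.clip(pos[:, 0], x0 + 3.6, x1 - 3.6, out=pos[:, 0])
    np.clip(pos[:, 1], y0 + 3.6, y1 - 3.6, out=pos[:, 1])
    return pos, states


def _headings(pos: np.ndarray, rng) -> np.ndarray:
    """Per-frame body heading: direction of the last displacement, carried
    forward through stationary stretches; random before the first move."""
    disp = np.diff(pos, axis=0)
    moving = np.linalg.norm(disp, axis=1) > 1e-6
    h = np.full(len(pos), np.nan)
    h[0] = rng.uniform(0, 2 * np.pi)
    idx = np.flatnonzero(moving) + 1
    h[idx] = np.arctan2(disp[idx - 1, 1], disp[idx - 1, 0])
    return pd.Series(h).ffill().to_numpy()


# ---------------------------------------------------------------------------
# Keypoint emission
# ---------------------------------------------------------------------------

def _emit_track(
    rng, pos, headings, states, fps: float, obs: ObservationParams,
    arena: ArenaConfig, body_scale: float, animal_id: str,
):
    n = len(pos)
    scale_long = np.ones(n)
    scale_lat = np.ones(n)
    rear = states == "rear"
    groom = states == "groom"
    scale_long[rear] = 0.55
    scale_lat[rear] = 0.8
    scale_long[groom] = 0.8

    local = TEMPLATE[None, :, :] * np.stack(
        [scale_long * body_scale, scale_lat * body_scale], axis=-1
    )[:, None, :]
    if groom.any():
        t = np.flatnonzero(groom)
        osc = 0.4 * np.sin(2 * np.pi * 4.0 * t / fps)
        local[t, KEYPOINT_INDEX["nose"], 0] += osc
    cos, sin = np.cos(headings), np.sin(headings)
    R = np.empty((n, 2, 2))
    R[:, 0, 0] = cos
    R[:, 0, 1] = -sin
    R[:, 1, 0] = sin
    R[:, 1, 1] = cos
    world = np.einsum("nij,nkj->nki", R, local) + pos[:, None, :]

    jit = rng.normal(0.0, obs.jitter_cm, size=world.shape)
    noisy = world + jit

    artifacts: list[tuple[int, str]] = []
    x0, y0, x1, y1 = arena.bounds
    if obs.teleport_rate > 0:
        # a glitch relocates the point somewhere else in the image: sample a
        # target inside the arena at least the minimum displacement away
        mask = rng.random((n, len(KEYPOINTS))) < obs.teleport_rate
        min_jump = obs.teleport_min_jump_cm
        for t, k in zip(*np.nonzero(mask)):
            for _ in range(64):
                target = rng.uniform([x0, y0], [x1, y1])
                if np.linalg.norm(target - noisy[t, k]) >= min_jump:
                    noisy[t, k] = target
                    artifacts.append((int(t), KEYPOINTS[k]))
                    break

    np.clip(noisy[:, :, 0], x0, x1, out=noisy[:, :, 0])
    np.clip(noisy[:, :, 1], y0, y1, out=noisy[:, :, 1])

    lik = rng.uniform(0.95, 1.0, size=(n, len(KEYPOINTS)))
    low = rng.random((n, len(KEYPOINTS))) < obs.lowlik_prob
    lik[low] = rng.uniform(0.1, 0.9, size=int(low.sum()))
    drop = rng.random((n, len(KEYPOINTS))) < obs.dropout_prob
    noisy[drop] = np.nan
    lik[drop] = np.nan

    px = noisy * 10.0 * obs.px_per_mm
    track = PoseTrack(
        animal_id=animal_id,
        xy=px,
        likelihood=lik,
        fps=fps,
        px_per_mm=obs.px_per_mm,
    )
    return track, artifacts


def _annotations(states: np.ndarray, label_set: tuple[str, ...]) -> AnnotationTrack:
    labels = np.array(
        [STATE_TO_LABEL.get(s, "none") for s in states], dtype=object
    )
    labels[~np.isin(labels, label_set)] = "none"
    return AnnotationTrack(labels=labels, label_set=label_set, source="machine")


# ---------------------------------------------------------------------------
# Public generators
# ---------------------------------------------------------------------------

def generate_session(scenario: SyntheticScenario, emit: bool = True) -> SessionData:
    """Simulate a full session; bit-identical for a given scenario seed.

    With ``emit=False`` only the latent ground truth is produced (used for
    large Monte-Carlo studies where keypoint tables are not needed).
    """
    if scenario.n_animals not in (1, 2):
        raise ValueError("n_animals must be 1 or 2")
    behavior = scenario.behavior or _single_behavior(1.0, 1.0, 0.35)
    if scenario.n_animals == 1 and any(
        s in ("follow", "sniff") for s in behavior.dwell_s
    ):
        raise ValueError("two-animal states requested with n_animals = 1")
    n = scenario.n_frames
    fps = scenario.fps
    ss = np.random.SeedSequence(scenario.seed)
    streams = [np.random.default_rng(c) for c in ss.spawn(6)]
    beh0, beh1, obs0, obs1, start_rng, _spare = streams

    x0, y0, x1, y1 = scenario.arena.bounds
    corner0 = np.array([x0 + 6.0, y0 + 6.0])
    corner1 = np.array([x1 - 6.0, y1 - 6.0])

    latent, states_all = [], []
    if scenario.n_animals == 2:
        juv_params = scenario.juvenile_behavior or _juvenile_behavior()
        juv_pos, juv_states = _latent_track(
            beh1, juv_params, scenario.arena, n, fps, corner1
        )
        sub_pos, sub_states = _latent_track(
            beh0, behavior, scenario.arena, n, fps, corner0, partner_pos=juv_pos
        )
        latent = [sub_pos, juv_pos]
        states_all = [sub_states, juv_states]
        label_set = SOCIAL_LABELS
        ids = ["subject", "juvenile"]
        body_scales = [behavior.body_scale, juv_params.body_scale]
    else:
        pos, states = _latent_track(beh0, behavior, scenario.arena, n, fps, corner0)
        latent = [pos]
        states_all = [states]
        label_set = SINGLE_LABELS
        ids = ["animal0"]
        body_scales = [behavior.body_scale]

    tracks: list[PoseTrack] = []
    artifacts: list[list[tuple[int, str]]] = []
    if emit:
        obs_streams = [obs0, obs1]
        for a in range(scenario.n_animals):
            head = _headings(latent[a], obs_streams[a])
            track, art = _emit_track(
                obs_streams[a], latent[a], head, states_all[a], fps,
                scenario.obs, scenario.arena, body_scales[a], ids[a],
            )
            tracks.append(track)
            artifacts.append(art)
    annotations = [_annotations(s, label_set) for s in states_all]
    return SessionData(
        tracks=tracks,
        annotations=annotations,
        arena=scenario.arena,
        fps=fps,
        latent_positions=latent,
        states=states_all,
        artifacts=artifacts,
        px_per_mm=scenario.obs.px_per_mm,
    )


def scripted_occupancy_session(
    seed: int,
    center_fraction: float = 0.5,
    duration_s: float = 600.0,
    fps: float = 30.0,
    obs: ObservationParams | None = None,
) -> SessionData:
    """Session with an exactly programmed center-zone occupancy fraction.

    The animal sits deep inside the center zone for the first
    ``round(center_fraction * n)`` frames and deep in a corner for the rest,
    both far from the zone boundary relative to the observation jitter, so
    the true center time is exact by construction.
    """
    if not 0 <= center_fraction <= 1:
        raise ValueError("center_fraction must be in [0, 1]")
    obs = obs or ObservationParams()
    arena = open_field_arena()
    n = int(round(duration_s * fps))
    k = int(round(center_fraction * n))
    inside = np.array([20.0, 20.0])
    outside = np.array([35.0, 35.0])
    pos = np.empty((n, 2))
    pos[:k] = inside
    pos[k:] = outside
    states = np.full(n, "rest", dtype=object)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    head = _headings(pos, rng)
    track, art = _emit_track(rng, pos, head, states, fps, obs, arena, 1.0, "animal0")
    return SessionData(
        tracks=[track],
        annotations=[_annotations(states, SINGLE_LABELS)],
        arena=arena,
        fps=fps,
        latent_positions=[pos],
        states=[states],
        artifacts=[art],
        px_per_mm=obs.px_per_mm,
        extras={"true_center_frames": k},
    )


def scripted_distance_session(
    seed: int,
    bin_distances_cm: tuple[float, ...] = (3600.0, 2400.0, 1200.0),
    bin_s: float = 600.0,
    fps: float = 30.0,
    speed_cm_s: float = 13.0,
    obs: ObservationParams | None = None,
) -> SessionData:
    """Session with programmed per-bin travel distances.

    Each bin starts with a locomotion burst at ``speed_cm_s`` long enough to
    cover the programmed distance, followed by rest; the default distances
    fall off across bins the way activity habituates over an open-field
    session.  The exact latent path length per bin is returned in
    ``extras["true_bin_distances_cm"]``.
    """
    obs = obs or ObservationParams()
    arena = open_field_arena()
    params = _single_behavior(1.0, 1.0, 0.35)
    params = replace(params, speed_range_cm_s=(speed_cm_s, speed_cm_s))
    bin_frames = int(round(bin_s * fps))
    n = bin_frames * len(bin_distances_cm)
    ss = np.random.SeedSequence(seed)
    walk_rng, obs_rng = [np.random.default_rng(c) for c in ss.spawn(2)]
    pos = np.empty((n, 2))
    states = np.full(n, "rest", dtype=object)
    p = np.array([8.0, 8.0])
    for b, dist in enumerate(bin_distances_cm):
        start = b * bin_frames
        move_frames = min(int(round(dist / speed_cm_s * fps)), bin_frames)
        states[start : start + move_frames] = "locomote"
        p = _fill_locomotion(walk_rng, params, arena, pos, start, move_frames, p, fps)
        pos[start + move_frames : start + bin_frames] = p
    head = _headings(pos, obs_rng)
    track, art = _emit_track(obs_rng, pos, head, states, fps, obs, arena, 1.0, "animal0")
    true_bins = [
        float(
            np.linalg.norm(
                np.diff(pos[b * bin_frames : (b + 1) * bin_frames], axis=0), axis=1
            ).sum()
        )
        for b in range(len(bin_distances_cm))
    ]
    # include the step crossing into the next bin (it belongs to this bin)
    for b in range(len(bin_distances_cm) - 1):
        true_bins[b] += float(
            np.linalg.norm(pos[(b + 1) * bin_frames] - pos[(b + 1) * bin_frames - 1])
        )
    return SessionData(
        tracks=[track],
        annotations=[_annotations(states, SINGLE_LABELS)],
        arena=arena,
        fps=fps,
        latent_positions=[pos],
        states=[states],
        artifacts=[art],
        px_per_mm=obs.px_per_mm,
        extras={"true_bin_distances_cm": true_bins},
    )


def generate_car_session(
    seed: int,
    exit_hazard_per_s: float,
    duration_s: float = 900.0,
    fps: float = 30.0,
    off_duration_s: tuple[float, float] = (5.0, 20.0),
    obs: ObservationParams | None = None,
) -> SessionData:
    """Cliff-avoidance session: platform dwell with exponential exit hazard.

    While on the platform the animal meanders within the platform disc; a
    jump moves it onto the arena floor for a random interval, after which the
    experimenter returns it to the platform (an instantaneous relocation in
    the track, as in the real assay).  Ground truth jump times are returned
    in ``extras["jump_times_s"]``.
    """
    obs = obs or ObservationParams()
    arena = car_arena(test_duration_s=duration_s)
    n = int(round(duration_s * fps))
    ss = np.random.SeedSequence(seed)
    beh_rng, obs_rng = [np.random.default_rng(c) for c in ss.spawn(2)]
    center = np.asarray(arena.platform_center)
    r_walk = arena.platform_diameter_cm / 2.0 - 2.5

    pos = np.empty((n, 2))
    states = np.full(n, "rest", dtype=object)
    jump_times: list[float] = []
    t = 0
    p = center.copy()
    while t < n:
        if exit_hazard_per_s > 0:
            dwell_s = beh_rng.exponential(1.0 / exit_hazard_per_s)
        else:
            dwell_s = duration_s + 1.0
        dwell = min(int(round(dwell_s * fps)) + 1, n - t)
        # platform meander: short waypoint hops inside the disc
        t_end = t + dwell
        while t < t_end:
            ang = beh_rng.uniform(0, 2 * np.pi)
            rad = beh_rng.uniform(0, r_walk)
            w = center + rad * np.array([np.cos(ang), np.sin(ang)])
            step = 8.0 / fps
            d = float(np.linalg.norm(w - p))
            k = min(max(int(np.ceil(d / step)), 1) + int(1.0 * fps), t_end - t)
            k_move = min(max(int(np.ceil(d / step)), 1), k)
            frac = np.minimum(np.arange(1, k_move + 1) * step / max(d, 1e-9), 1.0)
            pos[t : t + k_move] = p + frac[:, None] * (w - p)
            p = pos[t + k_move - 1].copy()
            if k > k_move:
                pos[t + k_move : t + k] = p
            t += k
        if t >= n:
            break
        # jump: animal leaves the platform onto the floor
        jump_times.append(t / fps)
        off_s = beh_rng.uniform(*off_duration_s)
        off = min(int(round(off_s * fps)), n - t)
        floor = np.array([beh_rng.uniform(4, 12), beh_rng.uniform(4, 12)])
        kf = min(off, max(int(np.ceil(float(np.linalg.norm(floor - p)) / (12.0 / fps))), 1))
        frac = np.minimum(np.arange(1, kf + 1) / kf, 1.0)
        pos[t : t + kf] = p + frac[:, None] * (floor - p)
        if off > kf:
            pos[t + kf : t + off] = floor
        states[t : t + off] = "locomote"
        t += off
        p = center.copy()  # experimenter returns the mouse to the platform
    head = _headings(pos, obs_rng)
    track, art = _emit_track(obs_rng, pos, head, states, fps, obs, arena, 1.0, "animal0")
    return SessionData(
        tracks=[track],
        annotations=[_annotations(states, SINGLE_LABELS)],
        arena=arena,
        fps=fps,
        latent_positions=[pos],
        states=[states],
        artifacts=[art],
        px_per_mm=obs.px_per_mm,
        extras={"jump_times_s": jump_times},
    )


def generate_ymaze_session(
    seed: int,
    p_alternate: float = 0.75,
    duration_s: float = 480.0,
    fps: float = 30.0,
    speed_cm_s: float = 10.0,
    junction_pause_s: float = 5.0,
    obs: ObservationParams | None = None,
) -> SessionData:
    """Y-maze session with an alternation-biased programmed entry sequence.

    With probability ``p_alternate`` the next arm is one not visited in the
    previous two entries, otherwise one of those two; the executed sequence
    is returned in ``extras["entry_sequence"]``.  The trajectory runs along
    arm centerlines to 80% of the arm length and back, pausing at the
    junction.
    """
    obs = obs or ObservationParams()
    arena = ymaze_arena(test_duration_s=duration_s)
    n = int(round(duration_s * fps))
    ss = np.random.SeedSequence(seed)
    beh_rng, obs_rng = [np.random.default_rng(c) for c in ss.spawn(2)]
    dirs = arena.arm_directions()
    depth = 0.8 * arena.arm_length_cm
    step = speed_cm_s / fps
    pause = int(round(junction_pause_s * fps))

    entries: list[int] = []
    pos = np.empty((n, 2))
    states = np.full(n, "locomote", dtype=object)
    t = 0
    origin = np.zeros(2)
    p = origin.copy()
    while t < n:
        if len(entries) >= 2:
            alt_set = [a for a in range(3) if a not in entries[-2:]]
            if beh_rng.random() < p_alternate and alt_set:
                arm = int(beh_rng.choice(alt_set))
            else:
                arm = int(beh_rng.choice(sorted(set(entries[-2:]))))
        else:
            arm = int(beh_rng.integers(0, 3))
        tip = origin + depth * dirs[arm]
        k_out = int(np.ceil(depth / step))
        path = []
        frac = np.minimum(np.arange(1, k_out + 1) * step / depth, 1.0)
        path.append(p + frac[:, None] * (tip - p))
        path.append(np.repeat(tip[None], int(1.0 * fps), axis=0))
        frac_b = np.minimum(np.arange(1, k_out + 1) * step / depth, 1.0)
        path.append(tip + frac_b[:, None] * (origin - tip))
        path.append(np.repeat(origin[None], pause, axis=0))
        path = np.concatenate(path, axis=0)
        k = min(len(path), n - t)
        pos[t : t + k] = path[:k]
        # ground truth: the entry registers once the body passes 30% of the
        # arm length (the same operational entry criterion the scorer uses)
        k_entry = int(np.ceil(0.3 * arena.arm_length_cm / step))
        if t + k_entry <= n:
            entries.append(arm)
        rest_start = t + 2 * k_out + int(1.0 * fps)
        states[min(rest_start, n) : min(rest_start + pause, n)] = "rest"
        p = pos[t + k - 1].copy()
        t += k
    head = _headings(pos, obs_rng)
    track, art = _emit_track(obs_rng, pos, head, states, fps, obs, arena, 1.0, "animal0")
    return SessionData(
        tracks=[track],
        annotations=[_annotations(states, SINGLE_LABELS)],
        arena=arena,
        fps=fps,
        latent_positions=[pos],
        states=[states],
        artifacts=[art],
        px_per_mm=obs.px_per_mm,
        extras={"entry_sequence": entries},
    )


# ---------------------------------------------------------------------------
# Stereology
# ---------------------------------------------------------------------------

def default_density_profile(
    n_dorsal: int = 45, n_ventral: int = 30, dorsal_level: float = 12.0,
    ventral_level: float = 8.0,
) -> np.ndarray:
    """Per-section expected newborn-neuron counts, dorsal sections first."""
    return np.concatenate(
        [np.full(n_dorsal, dorsal_level), np.full(n_ventral, ventral_level)]
    )


def generate_stereology(
    seed: int,
    profile: np.ndarray | None = None,
    offset: int = 0,
    interval: int = 6,
    n_dorsal: int = 45,
    poisson: bool = True,
    section_thickness_mm: float = 0.04,
    first_bregma_mm: float = -1.00,
) -> tuple[StereologyCounts, dict]:
    """Sampled section counts for a synthetic hippocampus.

    Sections are spaced ``section_thickness_mm`` apart starting at
    ``first_bregma_mm``; with the defaults the first ``n_dorsal`` sections
    are anterior to the -2.80 mm dorsal/ventral boundary.  Every
    ``interval``-th section from ``offset`` is sampled; counts are Poisson
    around the density profile (or the exact expectations with
    ``poisson=False``).  Returns the counts plus ground truth totals.
    """
    if profile is None:
        profile = default_density_profile(n_dorsal=n_dorsal)
    profile = np.asarray(profile, dtype=float)
    if not 0 <= offset < interval:
        raise ValueError("offset must lie in [0, interval)")
    n_sections = len(profile)
    bregma = first_bregma_mm - section_thickness_mm * np.arange(n_sections)
    dorsal_mask = bregma > -2.80
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    sampled = np.arange(offset, n_sections, interval)
    if poisson:
        counts = rng.poisson(profile[sampled]).astype(float)
    else:
        counts = profile[sampled]
    sections = pd.DataFrame({"bregma_mm": bregma[sampled], "counted": counts})
    totals = {
        "dorsal": int(dorsal_mask.sum()),
        "ventral": int((~dorsal_mask).sum()),
    }
    truth = {
        "dorsal": float(profile[dorsal_mask].sum()),
        "ventral": float(profile[~dorsal_mask].sum()),
        "whole": float(profile.sum()),
    }
    counts_obj = StereologyCounts(
        sections=sections, sampling_interval=interval, total_sections=totals
    )
    return counts_obj, truth
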