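"""Open-field center time, cliff-avoidance scoring, Y-maze alternation."""

import numpy as np
import pytest

from mousetrek.arenas import (
    ArenaConfig,
    arm_entry_sequence,
    car_arena,
    center_time,
    count_alternations,
    edge_time,
    open_field_arena,
    score_car,
    score_entry_sequence,
    ymaze_arena,
)
from mousetrek.kinematics import Trajectory


def _traj(points, fps=30.0):
    return Trajectory(np.asarray(points, dtype=float), fps=fps)


class TestCenterTime:
    def test_arena_center_counts_fully(self):
        traj = _traj(np.full((30 * 60, 2), 20.0))
        assert center_time(traj, open_field_arena()) == pytest.approx(60.0)

    def test_wall_position_counts_zero(self):
        # x = 5 cm is inside the 10 cm wall band, outside the 20x20 zone
        traj = _traj(np.column_stack([np.full(300, 5.0), np.full(300, 20.0)]))
        assert center_time(traj, open_field_arena()) == 0.0

    def test_boundary_is_closed(self):
        traj = _traj(np.full((30, 2), 10.0))  # exactly on the zone corner
        assert center_time(traj, open_field_arena()) == pytest.approx(1.0)

    def test_half_inside_path(self):
        n = 600
        pos = np.full((n, 2), 20.0)
        pos[n // 2 :, 0] = 35.0  # second half outside
        traj = _traj(pos)
        assert center_time(traj, open_field_arena()) == pytest.approx(
            traj.duration_s / 2
        )

    def test_center_plus_edge_equals_valid_time(self):
        rng = np.random.default_rng(5)
        pos = rng.uniform(0, 40, (1000, 2))
        pos[::17] = np.nan
        traj = _traj(pos)
        arena = open_field_arena()
        valid_s = np.isfinite(pos).all(axis=1).sum() / traj.fps
        assert center_time(traj, arena) + edge_time(traj, arena) == pytest.approx(
            valid_s
        )

    def test_requires_open_field(self):
        with pytest.raises(ValueError):
            center_time(_traj(np.zeros((10, 2))), car_arena())


class TestCar:
    def test_full_stay_censors_at_900(self):
        arena = car_arena()
        traj = _traj(np.full((30 * 900, 2), 20.0))
        res = score_car(traj, arena)
        assert res.latency_first_jump_s == 900.0
        assert res.n_jumps == 0
        assert res.censored

    def test_single_exit_scored_once(self):
        arena = car_arena()
        fps = 30
        pos = np.full((fps * 60, 2), 20.0)
        pos[fps * 12 :] = 5.0  # leaves at t = 12 s, never returns
        res = score_car(_traj(pos), arena)
        assert res.latency_first_jump_s == pytest.approx(12.0)
        assert res.n_jumps == 1
        assert not res.censored

    def test_three_programmed_cycles(self):
        arena = car_arena()
        fps = 30
        pos = np.full((fps * 300, 2), 20.0)
        exits = [50.0, 130.0, 210.0]
        for t0 in exits:
            a, b = int(t0 * fps), int((t0 + 10.0) * fps)
            pos[a:b] = 4.0
        res = score_car(_traj(pos), arena)
        assert res.n_jumps == 3
        assert res.latency_first_jump_s == pytest.approx(exits[0])

    def test_flicker_shorter_than_min_off_ignored(self):
        arena = car_arena()
        fps = 30
        pos = np.full((fps * 60, 2), 20.0)
        pos[100:103] = 4.0  # 0.1 s tracking flicker
        res = score_car(_traj(pos), arena)
        assert res.n_jumps == 0
        assert res.censored

    def test_invariant_under_resampling(self):
        arena = car_arena()
        fps = 30
        pos = np.full((fps * 120, 2), 20.0)
        pos[fps * 40 : fps * 55] = 4.0
        r30 = score_car(_traj(pos, fps=30), arena)
        r60 = score_car(_traj(np.repeat(pos, 2, axis=0), fps=60), arena)
        assert r30.n_jumps == r60.n_jumps == 1
        assert r30.latency_first_jump_s == pytest.approx(r60.latency_first_jump_s)

    def test_off_platform_start_warns(self):
        arena = car_arena()
        pos = np.full((30 * 20, 2), 4.0)
        pos[300:] = 20.0
        with pytest.warns(UserWarning, match="platform"):
            score_car(_traj(pos), arena)


def _brute_force_alternations(entries):
    """Independent scan: an entry alternates iff absent from the previous two."""
    count = 0
    for i, arm in enumerate(entries):
        if i >= 2 and arm not in {entries[i - 1], entries[i - 2]}:
            count += 1
    return count


class TestYmazeScoring:
    @pytest.mark.parametrize(
        "entries, n_alt, pct",
        [
            ([0, 0, 0, 0], 0, 0.0),
            ([0, 1, 2, 0, 1, 2], 4, pytest.approx(100 * 4 / 6)),
            ([0, 1, 0, 1], 0, 0.0),
        ],
    )
    def test_known_sequences(self, entries, n_alt, pct):
        res = score_entry_sequence(entries)
        assert res.n_alternations == n_alt
        assert res.alternation_pct == pct

    def test_perfect_alternation_is_100_under_conventional_denominator(self):
        res = score_entry_sequence([0, 1, 2] * 4)
        assert res.alternation_pct_conventional == pytest.approx(100.0)
        assert res.alternation_pct < 100.0  # literal total-entry denominator

    def test_fewer_than_three_entries_has_no_percentage(self):
        res = score_entry_sequence([0, 1])
        assert res.alternation_pct is None
        assert res.n_entries == 2

    def test_matches_brute_force_on_random_sequences(self, rng):
        for _ in range(1000):
            n = int(rng.integers(0, 13))
            seq = list(rng.integers(0, 3, n))
            assert count_alternations(seq) == _brute_force_alternations(seq)

    def test_alternation_bound(self, rng):
        for _ in range(200):
            seq = list(rng.integers(0, 3, int(rng.integers(0, 13))))
            assert count_alternations(seq) <= max(len(seq) - 2, 0)


class TestYmazeTrajectory:
    def test_scored_entries_match_programmed_sequence(self):
        from mousetrek.simulate import generate_ymaze_session

        for seed in (0, 1, 2):
            session = generate_ymaze_session(seed, p_alternate=0.7, duration_s=240)
            scored = arm_entry_sequence(session.true_trajectory(0), session.arena)
            assert scored == session.extras["entry_sequence"]

    def test_dwelling_in_one_arm_is_a_single_entry(self):
        arena = ymaze_arena()
        u = arena.arm_directions()[1]
        # go deep into arm 1 and oscillate around the distal threshold
        depth = np.concatenate(
            [np.linspace(0, 25, 60), 14 + 4 * np.sin(np.linspace(0, 8 * np.pi, 200))]
        )
        traj = _traj(np.outer(depth, u))
        assert arm_entry_sequence(traj, arena) == [1]


def test_arena_geometry_validation():
    with pytest.raises(ValueError, match="center_zone"):
        ArenaConfig(kind="open_field", bounds=(0, 0, 40, 40), center_zone=(30, 30, 41, 41))
    with pytest.raises(ValueError, match="platform"):
        ArenaConfig(
            kind="car", bounds=(0, 0, 40, 40),
            platform_center=(1.0, 20.0), platform_diameter_cm=12.5,
        )
    with pytest.raises(ValueError, match="duration"):
        ArenaConfig(kind="open_field", test_duration_s=0)
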