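"""Determinism, physical plausibility, and ground-truth consistency of the
synthetic session generator."""

import numpy as np
import pytest

import mousetrek as mt
from mousetrek.arenas import center_time
from mousetrek.behavior import bouts_from_binary
from mousetrek.simulate import (
    BehaviorParams,
    ObservationParams,
    SyntheticScenario,
    generate_car_session,
    generate_session,
    generate_ymaze_session,
    make_scenario,
    scripted_distance_session,
    scripted_occupancy_session,
)
from mousetrek.arenas import open_field_arena


def _rest_only_scenario(seed=0, duration_s=30.0, obs=None):
    params = BehaviorParams(
        dwell_s={"rest": 10.0}, trans={"rest": {"rest": 1.0}},
    )
    return SyntheticScenario(
        seed=seed,
        arena=open_field_arena(),
        duration_s=duration_s,
        behavior=params,
        obs=obs or ObservationParams(),
    )


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a = generate_session(make_scenario("control", seed=42, duration_s=30))
        b = generate_session(make_scenario("control", seed=42, duration_s=30))
        np.testing.assert_array_equal(a.tracks[0].xy, b.tracks[0].xy)
        np.testing.assert_array_equal(a.tracks[0].likelihood, b.tracks[0].likelihood)
        np.testing.assert_array_equal(a.states[0], b.states[0])

    def test_different_seeds_differ(self):
        a = generate_session(make_scenario("control", seed=1, duration_s=30))
        b = generate_session(make_scenario("control", seed=2, duration_s=30))
        assert not np.array_equal(a.latent_positions[0], b.latent_positions[0])

    def test_noise_channels_do_not_perturb_latent_path(self):
        clean = generate_session(
            make_scenario("control", seed=9, duration_s=30,
                          obs=ObservationParams(teleport_rate=0.0))
        )
        dirty = generate_session(
            make_scenario("control", seed=9, duration_s=30,
                          obs=ObservationParams(teleport_rate=0.01))
        )
        np.testing.assert_array_equal(
            clean.latent_positions[0], dirty.latent_positions[0]
        )


class TestPhysicalPlausibility:
    def test_keypoints_stay_inside_arena(self):
        s = generate_session(make_scenario("control", seed=3, duration_s=120))
        xy_cm = s.tracks[0].xy / (10.0 * s.px_per_mm)
        x0, y0, x1, y1 = s.arena.bounds
        finite = np.isfinite(xy_cm)
        assert np.nanmin(xy_cm[..., 0]) >= x0 and np.nanmax(xy_cm[..., 0]) <= x1
        assert np.nanmin(xy_cm[..., 1]) >= y0 and np.nanmax(xy_cm[..., 1]) <= y1

    def test_rest_only_zero_noise_session_has_zero_distance(self):
        obs = ObservationParams(jitter_cm=0.0, lowlik_prob=0.0, dropout_prob=0.0)
        s = generate_session(_rest_only_scenario(obs=obs))
        traj = mt.compute_trajectory(s.tracks[0])
        assert mt.travel_distance(traj) == pytest.approx(0.0, abs=1e-9)

    def test_state_occupancy_approaches_stationary_distribution(self):
        # embedded-chain stationary distribution weighted by dwell times
        scn = make_scenario("control", seed=5, duration_s=1800)
        p = scn.behavior
        states = sorted(p.dwell_s)
        P = np.zeros((len(states), len(states)))
        for i, s_from in enumerate(states):
            for s_to, prob in p.trans[s_from].items():
                P[i, states.index(s_to)] = prob
        evals, evecs = np.linalg.eig(P.T)
        pi = np.real(evecs[:, np.argmin(np.abs(evals - 1))])
        pi /= pi.sum()
        weights = pi * np.array([p.dwell_s[s] for s in states])
        expected = weights / weights.sum()
        occ = []
        for seed in (5, 6, 7):
            sess = generate_session(
                make_scenario("control", seed=seed, duration_s=1800), emit=False
            )
            occ.append(
                [np.mean(sess.states[0] == s) for s in states]
            )
        observed = np.mean(occ, axis=0)
        np.testing.assert_allclose(observed, expected, atol=0.02)

    def test_sniff_keeps_animals_in_contact(self):
        s = generate_session(
            make_scenario("control", seed=8, n_animals=2, duration_s=300), emit=False
        )
        iv = s.true_interval_series().distances
        sniffing = s.states[0] == "sniff"
        if sniffing.any():
            assert np.nanmax(iv[sniffing]) < 8.0

    def test_following_closes_distance(self):
        s = generate_session(
            make_scenario("control", seed=8, n_animals=2, duration_s=300), emit=False
        )
        iv = s.true_interval_series().distances
        follow = s.states[0] == "follow"
        assert follow.any()
        assert np.nanmean(iv[follow]) < np.nanmean(iv[~follow])


class TestGroundTruth:
    def test_bout_tables_round_trip_through_encoder(self):
        s = generate_session(make_scenario("control", seed=10, duration_s=300),
                             emit=False)
        for label in ("grooming", "rearing"):
            table = s.true_bouts(0, label)
            np.testing.assert_array_equal(
                table.binary(), s.annotations[0].binary(label)
            )
            again = bouts_from_binary(table.binary(), fps=s.fps, label=label)
            assert [(b.start_frame, b.end_frame) for b in table.bouts] == [
                (b.start_frame, b.end_frame) for b in again.bouts
            ]

    def test_scripted_occupancy_center_time_exact(self):
        s = scripted_occupancy_session(seed=4, center_fraction=0.5, duration_s=120)
        true_s = s.extras["true_center_frames"] / s.fps
        traj = mt.compute_trajectory(s.tracks[0])
        assert center_time(traj, s.arena) == pytest.approx(true_s, abs=1 / s.fps)

    def test_scripted_distance_bins_recovered(self):
        s = scripted_distance_session(seed=4, bin_distances_cm=(600.0, 300.0),
                                      bin_s=120.0)
        from mousetrek.quality import correct_outliers

        corrected, _ = correct_outliers(s.tracks[0])
        traj = mt.compute_trajectory(corrected)
        bins = mt.bin_metric(traj, 120.0, metric="distance", min_step_cm=0.2)
        for measured, truth in zip(
            [b["value"] for b in bins], s.extras["true_bin_distances_cm"]
        ):
            assert measured == pytest.approx(truth, rel=0.02)

    def test_car_ground_truth_jump_times_match_scoring(self):
        s = generate_car_session(seed=6, exit_hazard_per_s=0.01, duration_s=900)
        res = mt.score_car(s.true_trajectory(0), s.arena)
        truth = s.extras["jump_times_s"]
        assert res.n_jumps == len(truth)
        if truth:
            assert res.latency_first_jump_s == pytest.approx(truth[0], abs=1.0)

    def test_ymaze_entries_reproduced(self):
        s = generate_ymaze_session(seed=11, p_alternate=0.6, duration_s=240)
        res = mt.score_ymaze(s.true_trajectory(0), s.arena)
        assert res.entry_sequence == s.extras["entry_sequence"]


def test_two_animal_states_need_two_animals():
    params = BehaviorParams(
        dwell_s={"locomote": 4.0, "follow": 3.0},
        trans={"locomote": {"follow": 1.0}, "follow": {"locomote": 1.0}},
    )
    scn = SyntheticScenario(
        seed=0, arena=open_field_arena(), n_animals=1, duration_s=10, behavior=params
    )
    with pytest.raises(ValueError, match="two-animal"):
        generate_session(scn)


def test_transition_rows_must_sum_to_one():
    with pytest.raises(ValueError, match="sums"):
        BehaviorParams(dwell_s={"rest": 1.0}, trans={"rest": {"rest": 0.7}})
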