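"""Mislabel fraction, RMSE, and body-length-relative outlier correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mousetrek.pose_io import KEYPOINT_INDEX
from mousetrek.quality import (
    OutlierCorrectionParams,
    correct_outliers,
    median_body_length,
    mislabel_fraction,
    rmse_between,
)

from conftest import cm_to_px, make_track

NOSE = KEYPOINT_INDEX["nose"]
BC = KEYPOINT_INDEX["body_center"]


class TestMislabelFraction:
    def test_perfect_track_scores_zero(self):
        track = make_track(np.zeros((20, 2)) + 10.0, likelihood=1.0)
        assert mislabel_fraction(track).mislabel_fraction == 0.0

    def test_missing_nose_everywhere_scores_one(self):
        track = make_track(np.zeros((20, 2)) + 10.0)
        track.xy[:, NOSE] = np.nan
        rep = mislabel_fraction(track)
        assert rep.mislabel_fraction == 1.0
        assert rep.per_keypoint_flag_counts["nose"] == 20

    def test_low_likelihood_frame_count(self):
        # 7 of 100 frames carry one point at likelihood 0.5; threshold 0.9
        track = make_track(np.zeros((100, 2)) + 10.0, likelihood=1.0)
        flagged = [3, 17, 30, 44, 58, 71, 99]
        for f in flagged:
            track.likelihood[f, NOSE] = 0.5
        rep = mislabel_fraction(track, likelihood_threshold=0.9)
        assert rep.mislabel_fraction == pytest.approx(0.07)
        assert rep.n_flagged == 7
        assert rep.n_points_flagged == 7

    @given(
        lik=st.lists(st.floats(min_value=0, max_value=1), min_size=7, max_size=7),
        t1=st.floats(min_value=0.05, max_value=1.0),
        t2=st.floats(min_value=0.05, max_value=1.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_threshold(self, lik, t1, t2):
        track = make_track(np.zeros((8, 2)) + 10.0)
        track.likelihood[:] = np.array(lik)[None, :]
        lo, hi = min(t1, t2), max(t1, t2)
        assert (
            mislabel_fraction(track, lo).mislabel_fraction
            <= mislabel_fraction(track, hi).mislabel_fraction
        )

    def test_empty_track_rejected(self):
        track = make_track(np.zeros((1, 2)))
        track.xy = track.xy[:0]
        track.likelihood = track.likelihood[:0]
        with pytest.raises(ValueError):
            mislabel_fraction(track)


class TestRmse:
    def test_identical_tracks_zero(self):
        t = make_track(np.random.default_rng(0).uniform(5, 35, (10, 2)))
        assert rmse_between(t, t.copy()).rmse == 0.0

    def test_constant_offset_is_hypotenuse(self):
        ref = make_track(np.zeros((10, 2)) + 20.0)
        pred = ref.copy()
        pred.xy = pred.xy + np.array([3.0, 4.0])
        res = rmse_between(ref, pred)
        assert res.rmse == pytest.approx(5.0)
        assert res.n_pairs == 70

    def test_single_outlier_scales_with_pair_count(self):
        n = 25
        ref = make_track(np.zeros((n, 2)) + 20.0)
        pred = ref.copy()
        pred.xy = pred.xy.copy()
        pred.xy[0, NOSE, 0] += 10.0
        expected = np.sqrt(100.0 / (7 * n))
        assert rmse_between(ref, pred).rmse == pytest.approx(expected)

    def test_symmetric_and_excludes_missing(self):
        ref = make_track(np.zeros((6, 2)) + 20.0)
        pred = ref.copy()
        pred.xy = pred.xy + 2.0
        pred.xy[1, 3] = np.nan
        a, b = rmse_between(ref, pred), rmse_between(pred, ref)
        assert a.rmse == pytest.approx(b.rmse)
        assert a.n_pairs == b.n_pairs == 6 * 7 - 1

    def test_no_overlap_is_an_error(self):
        ref = make_track(np.zeros((4, 2)) + 20.0)
        pred = ref.copy()
        pred.xy = np.full_like(pred.xy, np.nan)
        with pytest.raises(ValueError, match="overlapping"):
            rmse_between(ref, pred)


def _straight_walk(n=60, step=0.1):
    pos = np.cumsum(np.full((n, 2), step), axis=0) + 10.0
    return make_track(pos)


class TestOutlierCorrection:
    def test_smooth_track_untouched(self):
        track = _straight_walk()
        out, log = correct_outliers(track)
        assert log == []
        np.testing.assert_array_equal(out.xy, track.xy)

    def test_single_teleport_yields_one_movement_correction(self):
        track = _straight_walk()
        L_px = median_body_length(track)
        before = track.xy[30, NOSE].copy()
        track.xy[30, NOSE] += 5.0 * L_px  # one-frame teleport, then returns
        out, log = correct_outliers(track)
        assert len(log) == 1
        assert (log[0].frame, log[0].keypoint, log[0].reason) == (30, "nose", "movement")
        np.testing.assert_allclose(out.xy[30, NOSE], track.xy[29, NOSE])

    def test_pinned_location_outlier_corrected_every_frame(self):
        # nose drifts to 2.2 L from the body center in one sub-criterion step,
        # then sticks there: the movement rule passes, the location rule fires
        n = 40
        track = make_track(np.zeros((n, 2)) + 20.0)
        L_px = median_body_length(track)
        bc = track.xy[0, BC]
        near = bc + np.array([0.9 * L_px, 0.0])
        pinned = bc + np.array([2.6 * L_px, 0.0])
        track.xy[:, NOSE] = near
        track.xy[10:20, NOSE] = pinned
        out, log = correct_outliers(track)
        reasons = [(c.frame, c.reason) for c in log]
        assert reasons == [(f, "location") for f in range(10, 20)]
        np.testing.assert_allclose(out.xy[10:20, NOSE], np.broadcast_to(near, (10, 2)))

    def test_idempotent_under_noise_and_artifacts(self):
        from mousetrek.simulate import ObservationParams, generate_session, make_scenario

        scn = make_scenario(
            "control", seed=7, duration_s=60,
            obs=ObservationParams(teleport_rate=0.002),
        )
        session = generate_session(scn)
        once, log1 = correct_outliers(session.tracks[0])
        twice, log2 = correct_outliers(once)
        assert len(log1) > 0
        assert log2 == []
        np.testing.assert_array_equal(once.xy, twice.xy)

    def test_insufficient_body_length_coverage(self):
        track = _straight_walk(n=20)
        track.xy[: 15, NOSE] = np.nan
        with pytest.raises(ValueError, match="body length"):
            correct_outliers(track)

    def test_criteria_must_be_positive(self):
        with pytest.raises(ValueError):
            OutlierCorrectionParams(movement_criterion=0.0)
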