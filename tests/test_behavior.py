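"""Bout encoding, frame classifier training, and human-machine agreement."""

import numpy as np
import pandas as pd
import pytest

from mousetrek.behavior import (
    bouts_from_binary,
    frame_agreement,
    predict_bouts,
    session_agreement,
    train_classifier,
)
from mousetrek.pose_io import AnnotationTrack

FPS = 30.0


def _brute_force_rle(bits):
    """Independent run-length encoder: explicit frame-by-frame scan."""
    runs = []
    start = None
    for i, b in enumerate(bits):
        if b and start is None:
            start = i
        if not b and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(bits) - 1))
    return runs


class TestBoutEncoding:
    def test_matches_brute_force_on_random_sequences(self, rng):
        for _ in range(1000):
            bits = rng.random(int(rng.integers(0, 40))) < 0.4
            table = bouts_from_binary(bits, fps=FPS)
            got = [(b.start_frame, b.end_frame) for b in table.bouts]
            assert got == _brute_force_rle(bits)

    def test_empty_input_gives_empty_table(self):
        table = bouts_from_binary(np.zeros(100, dtype=bool), fps=FPS)
        assert table.frequency == 0
        assert table.total_duration_s == 0.0

    def test_ninety_frame_run_is_three_seconds(self):
        bits = np.zeros(300, dtype=bool)
        bits[100:190] = True
        table = bouts_from_binary(bits, fps=30.0)
        assert table.frequency == 1
        assert table.total_duration_s == pytest.approx(3.0)

    def test_short_gap_merges_runs(self):
        bits = np.zeros(100, dtype=bool)
        bits[10:20] = True
        bits[24:34] = True  # 4-frame gap < 0.2 s merge gap at 30 fps
        table = bouts_from_binary(bits, fps=30.0, merge_gap_s=0.2)
        assert table.frequency == 1
        assert (table.bouts[0].start_frame, table.bouts[0].end_frame) == (10, 33)

    def test_long_gap_stays_split(self):
        bits = np.zeros(100, dtype=bool)
        bits[10:20] = True
        bits[40:50] = True
        table = bouts_from_binary(bits, fps=30.0, merge_gap_s=0.2)
        assert table.frequency == 2

    def test_minimum_bout_length_drops_short_runs(self):
        bits = np.zeros(100, dtype=bool)
        bits[10:14] = True  # 4 frames < 0.3 s at 30 fps
        bits[50:70] = True
        table = bouts_from_binary(bits, fps=30.0, min_bout_s=0.3)
        assert table.frequency == 1
        assert table.bouts[0].start_frame == 50

    def test_binary_round_trip(self, rng):
        bits = rng.random(500) < 0.3
        table = bouts_from_binary(bits, fps=FPS)
        np.testing.assert_array_equal(table.binary(), bits)


def _feature_frame(signal, n_noise=3, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"signal": signal})
    for i in range(n_noise):
        df[f"noise_{i}"] = rng.normal(size=len(signal))
    df["valid"] = True
    return df


def _annotations(y):
    labels = np.where(y, "grooming", "none").astype(object)
    return AnnotationTrack(labels=labels, label_set=("none", "grooming"))


class TestClassifier:
    def test_separable_problem_reaches_perfect_f1(self, rng):
        y = rng.random(2000) < 0.3
        signal = y.astype(float) * 2.0 + rng.normal(0, 0.1, len(y))
        model = train_classifier(_feature_frame(signal), _annotations(y), "grooming", seed=1)
        assert model.report.f1 == pytest.approx(1.0)

    def test_permuted_labels_score_near_chance(self, rng):
        y = rng.random(2000) < 0.3
        signal = y.astype(float) * 2.0 + rng.normal(0, 0.1, len(y))
        y_perm = rng.permutation(y)
        model = train_classifier(
            _feature_frame(signal), _annotations(y_perm), "grooming", seed=1
        )
        # with independent labels, precision hovers at prevalence; F1 is far
        # below the separable case
        assert model.report.f1 < 0.55

    def test_same_seed_reproduces_predictions(self, rng):
        y = rng.random(800) < 0.4
        signal = y.astype(float) + rng.normal(0, 0.5, len(y))
        feats = _feature_frame(signal)
        ann = _annotations(y)
        m1 = train_classifier(feats, ann, "grooming", seed=7)
        m2 = train_classifier(feats, ann, "grooming", seed=7)
        np.testing.assert_array_equal(m1.predict_proba(feats), m2.predict_proba(feats))

    def test_single_class_rejected(self):
        feats = _feature_frame(np.zeros(50))
        ann = _annotations(np.zeros(50, dtype=bool))
        with pytest.raises(ValueError, match="degenerate"):
            train_classifier(feats, ann, "grooming")

    def test_mismatched_lengths_rejected(self, rng):
        feats = _feature_frame(np.zeros(50))
        ann = _annotations(rng.random(49) < 0.5)
        with pytest.raises(ValueError, match="annotation"):
            train_classifier(feats, ann, "grooming")

    def test_predict_bouts_checks_feature_contract(self, rng):
        y = rng.random(300) < 0.4
        feats = _feature_frame(y.astype(float))
        model = train_classifier(feats, _annotations(y), "grooming", seed=0)
        wrong = feats.rename(columns={"noise_0": "other"})
        with pytest.raises(ValueError, match="other"):
            predict_bouts(model, wrong, fps=FPS)

    def test_predict_bouts_end_to_end(self, rng):
        y = np.zeros(600, dtype=bool)
        y[100:250] = True
        y[400:500] = True
        signal = y.astype(float) * 3.0 + rng.normal(0, 0.1, len(y))
        feats = _feature_frame(signal)
        model = train_classifier(feats, _annotations(y), "grooming", seed=2)
        table = predict_bouts(model, feats, fps=FPS)
        assert table.frequency == 2
        assert table.total_duration_s == pytest.approx(250 / FPS, rel=0.05)


class TestAgreement:
    def test_identical_sources_agree_perfectly(self, rng):
        human = rng.random(1000) < 0.2
        res = frame_agreement(human.copy(), human, fps=FPS)
        assert res.f1 == 1.0
        assert res.machine_frequency == res.human_frequency

    def test_one_frame_shift_on_long_bouts(self):
        human = np.zeros(1000, dtype=bool)
        human[100:400] = True
        human[600:900] = True
        machine = np.roll(human, 1)
        res = frame_agreement(machine, human, fps=FPS)
        assert res.f1 > 0.99
        assert res.machine_frequency == res.human_frequency == 2
        assert res.machine_duration_s == pytest.approx(res.human_duration_s)

    def test_silent_machine_has_zero_recall(self):
        human = np.zeros(200, dtype=bool)
        human[50:100] = True
        res = frame_agreement(np.zeros(200, dtype=bool), human, fps=FPS)
        assert res.recall == 0.0

    def test_session_correlation_needs_three_sessions(self, rng):
        pairs = [(rng.random(200) < 0.3,) * 2 for _ in range(2)]
        out = session_agreement([(m.copy(), h) for m, h in pairs], fps=FPS)
        assert np.isnan(out["r_frequency"])

    def test_session_correlation_perfect_for_identical(self, rng):
        pairs = []
        for i in range(4):
            h = rng.random(300 + 50 * i) < (0.1 + 0.1 * i)
            pairs.append((h.copy(), h))
        out = session_agreement(pairs, fps=FPS)
        assert out["r_frequency"] == pytest.approx(1.0)
        assert out["r_duration"] == pytest.approx(1.0)
        assert out["f1"] == 1.0
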