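"""Supervised frame classification and bout-level behavior summaries.

A behavior classifier is trained per label (grooming, rearing, following,
sniffing) on engineered pose features against human frame annotations, using
a random forest of 100 trees with a fixed seed — reproducibility is
prioritized over matching any particular toolkit's internals.  Predicted
per-frame probabilities are post-processed into bouts: frames above the
probability threshold become positive, positive runs separated by gaps no
longer than the merge gap are joined, and runs shorter than the minimum bout
length are dropped.  Sessions are summarized by bout frequency (count) and
total duration (s), the same quantities a human scorer reports, which makes
human-machine agreement a direct comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .pose_io import AnnotationTrack

DEFAULT_THRESHOLD = 0.5
DEFAULT_MIN_BOUT_S = 0.3
DEFAULT_MERGE_GAP_S = 0.2


@dataclass
class Bout:
    label: str
    start_frame: int
    end_frame: int  # inclusive
    duration_s: float


@dataclass
class BoutTable:
    """Non-overlapping labeled behavior intervals for one session."""

    bouts: list[Bout]
    n_frames: int
    fps: float

    @property
    def frequency(self) -> int:
        return len(self.bouts)

    @property
    def total_duration_s(self) -> float:
        return float(sum(b.duration_s for b in self.bouts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "label": b.label,
                    "start_frame": b.start_frame,
                    "end_frame": b.end_frame,
                    "duration_s": b.duration_s,
                }
                for b in self.bouts
            ]
        )

    def binary(self) -> np.ndarray:
        """Dense per-frame indicator reconstructed from the bout list."""
        out = np.zeros(self.n_frames, dtype=bool)
        for b in self.bouts:
            out[b.start_frame : b.end_frame + 1] = True
        return out


def bouts_from_binary(
    positive: np.ndarray,
    fps: float,
    label: str = "behavior",
    min_bout_s: float = 0.0,
    merge_gap_s: float = 0.0,
) -> BoutTable:
    """Run-length encode a per-frame indicator into a bout table.

    Gaps of at most ``merge_gap_s`` between positive runs are merged first;
    merged runs shorter than ``min_bout_s`` are then dropped.  Duration of a
    run of f frames is f / fps.
    """
    positive = np.asarray(positive, dtype=bool)
    n = len(positive)
    runs = _runs(positive)
    max_gap = int(round(merge_gap_s * fps))
    if max_gap > 0 and len(runs) > 1:
        merged = [runs[0]]
        for s, e in runs[1:]:
            ps, pe = merged[-1]
            if s - pe - 1 <= max_gap:
                merged[-1] = (ps, e)
            else:
                merged.append((s, e))
        runs = merged
    min_frames = int(np.ceil(min_bout_s * fps - 1e-9))
    bouts = [
        Bout(label=label, start_frame=s, end_frame=e, duration_s=(e - s + 1) / fps)
        for s, e in runs
        if (e - s + 1) >= max(min_frames, 1)
    ]
    return BoutTable(bouts=bouts, n_frames=n, fps=fps)


def _runs(positive: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as (start, end-inclusive) pairs."""
    if len(positive) == 0:
        return []
    padded = np.concatenate([[False], positive, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def bouts_from_labels(track: AnnotationTrack, label: str, fps: float) -> BoutTable:
    """Bout table of one behavior from a dense annotation track (no filtering)."""
    return bouts_from_binary(track.binary(label), fps=fps, label=label)


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------

@dataclass
class TrainingReport:
    n_train: int
    n_test: int
    precision: float
    recall: float
    f1: float
    prevalence: float


@dataclass
class ClassifierModel:
    """A per-frame probability model for one behavior label."""

    label: str
    estimator: RandomForestClassifier
    feature_names: list[str]
    threshold: float = DEFAULT_THRESHOLD
    min_bout_s: float = DEFAULT_MIN_BOUT_S
    merge_gap_s: float = DEFAULT_MERGE_GAP_S
    seed: int = 0
    report: TrainingReport | None = None

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        """Per-frame probability of the behavior; invalid rows score 0."""
        missing = [c for c in self.feature_names if c not in features.columns]
        extra = [
            c for c in features.columns
            if c not in self.feature_names and c != "valid"
        ]
        if missing or extra:
            raise ValueError(
                f"feature columns do not match training: missing={missing}, "
                f"unexpected={extra}"
            )
        X = features[self.feature_names].to_numpy(dtype=float)
        ok = np.isfinite(X).all(axis=1)
        if "valid" in features.columns:
            ok &= features["valid"].to_numpy(dtype=bool)
        proba = np.zeros(len(X))
        if ok.any():
            positive_col = list(self.estimator.classes_).index(True)
            proba[ok] = self.estimator.predict_proba(X[ok])[:, positive_col]
        return proba


def train_classifier(
    features: pd.DataFrame,
    annotations: AnnotationTrack,
    label: str,
    seed: int = 0,
    n_estimators: int = 100,
    test_fraction: float = 0.2,
    sample_stride: int = 1,
    **model_kwargs,
) -> ClassifierModel:
    """Fit a random-forest frame classifier for one behavior label.

    A stratified held-out split reports frame-level precision/recall/F1.
    Training is reproducible for a given seed.  ``sample_stride`` subsamples
    frames to cut training cost on long sessions (adjacent frames carry
    nearly duplicate information).
    """
    if len(features) != annotations.n_frames:
        raise ValueError(
            f"feature rows ({len(features)}) and annotation frames "
            f"({annotations.n_frames}) differ"
        )
    from .features import feature_names as _fn

    names = _fn(features)
    X = features[names].to_numpy(dtype=float)
    y = annotations.binary(label)
    ok = np.isfinite(X).all(axis=1)
    if "valid" in features.columns:
        ok &= features["valid"].to_numpy(dtype=bool)
    X, y = X[ok][::sample_stride], y[ok][::sample_stride]
    if y.all() or not y.any():
        raise ValueError(
            f"degenerate training set: label {label!r} must have both classes"
        )
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_fraction, random_state=seed, stratify=y
    )
    rf = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1, **model_kwargs
    )
    rf.fit(X_tr, y_tr)
    positive_col = list(rf.classes_).index(True)
    pred = rf.predict_proba(X_te)[:, positive_col] >= DEFAULT_THRESHOLD
    tp = int((pred & y_te).sum())
    fp = int((pred & ~y_te).sum())
    fn = int((~pred & y_te).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    report = TrainingReport(
        n_train=len(y_tr),
        n_test=len(y_te),
        precision=precision,
        recall=recall,
        f1=f1,
        prevalence=float(y.mean()),
    )
    return ClassifierModel(
        label=label,
        estimator=rf,
        feature_names=names,
        seed=seed,
        report=report,
    )


def predict_bouts(
    model: ClassifierModel,
    features: pd.DataFrame,
    fps: float,
    threshold: float | None = None,
    min_bout_s: float | None = None,
    merge_gap_s: float | None = None,
) -> BoutTable:
    """Classify frames and post-process into a bout table."""
    proba = model.predict_proba(features)
    positive = proba >= (threshold if threshold is not None else model.threshold)
    return bouts_from_binary(
        positive,
        fps=fps,
        label=model.label,
        min_bout_s=min_bout_s if min_bout_s is not None else model.min_bout_s,
        merge_gap_s=merge_gap_s if merge_gap_s is not None else model.merge_gap_s,
    )


# ---------------------------------------------------------------------------
# Human-machine agreement
# ---------------------------------------------------------------------------

@dataclass
class AgreementResult:
    precision: float
    recall: float
    f1: float
    machine_frequency: int
    human_frequency: int
    machine_duration_s: float
    human_duration_s: float


def frame_agreement(machine: np.ndarray, human: np.ndarray, fps: float,
                    label: str = "behavior") -> AgreementResult:
    """Frame-level precision/recall/F1 of machine vs human indicators,
    plus the bout frequency and total duration each source reports."""
    machine = np.asarray(machine, dtype=bool)
    human = np.asarray(human, dtype=bool)
    if machine.shape != human.shape:
        raise ValueError("machine and human tracks differ in length")
    tp = int((machine & human).sum())
    fp = int((machine & ~human).sum())
    fn = int((~machine & human).sum())
    precision = tp / (tp + fp) if tp + fp else (1.0 if fn == 0 else 0.0)
    recall = tp / (tp + fn) if tp + fn else 1.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    m_b = bouts_from_binary(machine, fps, label)
    h_b = bouts_from_binary(human, fps, label)
    return AgreementResult(
        precision=precision,
        recall=recall,
        f1=f1,
        machine_frequency=m_b.frequency,
        human_frequency=h_b.frequency,
        machine_duration_s=m_b.total_duration_s,
        human_duration_s=h_b.total_duration_s,
    )


def session_agreement(
    pairs: list[tuple[np.ndarray, np.ndarray]], fps: float
) -> dict:
    """Across-session agreement: Pearson r of per-session frequency and
    duration between machine and human, plus pooled frame-level scores.

    With fewer than 3 sessions the correlations are reported as NaN.
    """
    per = [frame_agreement(m, h, fps) for m, h in pairs]
    mfreq = [a.machine_frequency for a in per]
    hfreq = [a.human_frequency for a in per]
    mdur = [a.machine_duration_s for a in per]
    hdur = [a.human_duration_s for a in per]
    if len(pairs) >= 3 and np.std(mfreq) > 0 and np.std(hfreq) > 0:
        r_freq = float(stats.pearsonr(mfreq, hfreq).statistic)
    else:
        r_freq = float("nan")
    if len(pairs) >= 3 and np.std(mdur) > 0 and np.std(hdur) > 0:
        r_dur = float(stats.pearsonr(mdur, hdur).statistic)
    else:
        r_dur = float("nan")
    pooled_m = np.concatenate([np.asarray(m, dtype=bool) for m, _ in pairs])
    pooled_h = np.concatenate([np.asarray(h, dtype=bool) for _, h in pairs])
    pooled = frame_agreement(pooled_m, pooled_h, fps)
    return {
        "r_frequency": r_freq,
        "r_duration": r_dur,
        "precision": pooled.precision,
        "recall": pooled.recall,
        "f1": pooled.f1,
        "per_session": per,
    }
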