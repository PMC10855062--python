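"""Reproducible validation studies run against the synthetic generator.

Each function performs one self-contained study end to end — generate
synthetic data with known ground truth, push it through the analysis
pipeline, and measure recovery or calibration — and returns a plain dict of
numbers.  All randomness derives from the single ``seed`` argument, so a
study is exactly reproducible.  These studies back both the test suite and
the ``scripts/acceptance.py`` report.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import simulate
from .arenas import center_time, score_car, score_ymaze
from .behavior import predict_bouts, train_classifier
from .features import extract_features
from .kinematics import compute_trajectory, travel_distance
from .pose_io import AnnotationTrack, RecordingSpec, expected_frame_count
from .quality import correct_outliers
from .social import correlation_length_frames, ks_compare
from .stereology import estimate_total

#: Displacement threshold used when recovering travel distance from noisy
#: keypoints: ~5x the centroid jitter scale of the default observation model
#: (sigma 0.1 cm per keypoint / sqrt(7) points), suppressing the Rayleigh
#: noise floor on a stationary animal while passing every locomotion step.
DISTANCE_MIN_STEP_CM = 0.2


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def frame_accounting() -> dict:
    """Printed frame counts for the standard recording formats."""
    per_10min = expected_frame_count(RecordingSpec(600, 30))
    per_30min = expected_frame_count(RecordingSpec(1800, 30))
    return {
        "frames_10min_session": per_10min,
        "frames_15x30min_sessions": 15 * per_30min,
        "frames_15x10min_sessions": 15 * per_10min,
    }


def car_censoring(seed: int) -> dict:
    """A full-duration no-jump session scored through the pipeline."""
    session = simulate.generate_car_session(seed, exit_hazard_per_s=0.0)
    traj = compute_trajectory(session.tracks[0])
    res = score_car(traj, session.arena)
    return {
        "latency_s": res.latency_first_jump_s,
        "n_jumps": res.n_jumps,
        "censored": res.censored,
    }


def distance_recovery(seed: int, duration_s: float = 1800.0) -> dict:
    """Travel distance from noisy keypoints vs latent ground truth."""
    scn = simulate.make_scenario("control", seed=seed, duration_s=duration_s)
    session = simulate.generate_session(scn)
    true_cm = travel_distance(session.true_trajectory(0))
    corrected, _ = correct_outliers(session.tracks[0])
    traj = compute_trajectory(corrected)
    measured_cm = travel_distance(traj, min_step_cm=DISTANCE_MIN_STEP_CM)
    return {
        "true_cm": true_cm,
        "measured_cm": measured_cm,
        "rel_error_pct": 100.0 * abs(measured_cm - true_cm) / true_cm,
    }


def center_time_recovery(seed: int, duration_s: float = 600.0) -> dict:
    """Center-zone dwell on a programmed-occupancy session."""
    session = simulate.scripted_occupancy_session(
        seed, center_fraction=0.5, duration_s=duration_s
    )
    true_s = session.extras["true_center_frames"] / session.fps
    traj = compute_trajectory(session.tracks[0])
    measured_s = center_time(traj, session.arena)
    return {
        "true_s": true_s,
        "measured_s": measured_s,
        "error_frames": abs(measured_s - true_s) * session.fps,
    }


def outlier_recall(seed: int, duration_s: float = 600.0) -> dict:
    """Recall of injected single-frame teleport artifacts."""
    scn = simulate.make_scenario(
        "control", seed=seed, duration_s=duration_s,
        obs=simulate.ObservationParams(teleport_rate=0.001),
    )
    session = simulate.generate_session(scn)
    injected = set(session.artifacts[0])
    _, log = correct_outliers(session.tracks[0])
    caught = {(c.frame, c.keypoint) for c in log}
    n_caught = len(injected & caught)
    return {
        "n_injected": len(injected),
        "n_caught": n_caught,
        "recall_pct": 100.0 * n_caught / len(injected) if injected else float("nan"),
    }


def ks_type1(
    seed: int, n_pairs: int = 1000, duration_s: float = 600.0, n_calibration: int = 5
) -> dict:
    """Type-I error of the strided K-S comparison on identical presets.

    The subsampling stride is set to the largest interval-distance
    correlation length measured over ``n_calibration`` independent sessions,
    then ``n_pairs`` fresh session pairs generated from identical parameters
    are compared at alpha = 0.05.
    """
    seeds = _child_seeds(seed, n_calibration + 2 * n_pairs)

    def _series(s):
        scn = simulate.make_scenario(
            "control", seed=int(s), n_animals=2, duration_s=duration_s
        )
        return simulate.generate_session(scn, emit=False).true_interval_series()

    stride = max(
        correlation_length_frames(_series(s)) for s in seeds[:n_calibration]
    )
    rejections = 0
    for i in range(n_pairs):
        a = _series(seeds[n_calibration + 2 * i])
        b = _series(seeds[n_calibration + 2 * i + 1])
        if ks_compare(a, b, subsample_stride=stride).p_value < 0.05:
            rejections += 1
    return {
        "stride_frames": int(stride),
        "n_pairs": n_pairs,
        "rejections": rejections,
        "type1_rate_pct": 100.0 * rejections / n_pairs,
    }


def stereology_worked_example() -> dict:
    """The scaled-mean estimator on the canonical section counts."""
    sections = pd.DataFrame(
        {
            "bregma_mm": [-2.0] * 8 + [-3.2] * 8,
            "counted": [10] * 8 + [5, 5, 5, 5, 4, 3, 2, 1],
        }
    )
    from .stereology import StereologyCounts

    est = estimate_total(StereologyCounts(sections=sections))
    return {"dorsal": est.dorsal, "ventral": est.ventral, "whole": est.whole}


def stereology_offset_bias(seed: int, poisson_reps: int = 120) -> dict:
    """Mean estimator bias over sampling phases on a simulated hippocampus.

    Noise-free uniform profile: the offset-mean is exactly the true total.
    With Poisson counting noise, the Monte-Carlo mean over replicates cycling
    through offsets stays within sampling error of the truth.
    """
    profile = simulate.default_density_profile(dorsal_level=12.0, ventral_level=6.0)
    uniform = simulate.default_density_profile(dorsal_level=10.0, ventral_level=10.0)
    exact = []
    for offset in range(6):
        counts, truth_u = simulate.generate_stereology(
            seed, profile=uniform, offset=offset, poisson=False
        )
        exact.append(estimate_total(counts).whole)
    exact_bias_pct = 100.0 * (np.mean(exact) - truth_u["whole"]) / truth_u["whole"]

    seeds = _child_seeds(seed, poisson_reps)
    estimates = []
    for rep, s in enumerate(seeds):
        counts, truth = simulate.generate_stereology(
            int(s), profile=profile, offset=rep % 6, poisson=True
        )
        estimates.append(estimate_total(counts).whole)
    mc_bias_pct = 100.0 * (np.mean(estimates) - truth["whole"]) / truth["whole"]
    return {
        "exact_offset_mean_bias_pct": float(exact_bias_pct),
        "poisson_mc_bias_pct": float(mc_bias_pct),
        "true_total": truth["whole"],
        "mc_mean_estimate": float(np.mean(estimates)),
    }


# ---------------------------------------------------------------------------
# Directional control vs PNE-like study
# ---------------------------------------------------------------------------

def _train_social_classifiers(train_seeds, labels=("following", "sniffing")):
    feats_list, ann_list = [], []
    for s in train_seeds:
        scn = simulate.make_scenario(
            "control", seed=int(s), n_animals=2, duration_s=600
        )
        session = simulate.generate_session(scn)
        feats_list.append(extract_features(session.tracks))
        ann_list.append(session.annotations[0])
    feats = pd.concat(feats_list, ignore_index=True)
    ann = AnnotationTrack(
        labels=np.concatenate([a.labels for a in ann_list]),
        label_set=ann_list[0].label_set,
        source="machine",
    )
    return {
        label: train_classifier(feats, ann, label, seed=0, sample_stride=3)
        for label in labels
    }


def directional_study(seed: int, n_per_group: int = 10) -> dict:
    """Control vs PNE-like presets across all four assays, end to end.

    Ten simulated animals per group run through the full pipeline: open-field
    center time from keypoints, machine-classified following/sniffing bout
    frequency and duration in the two-animal test, cliff-avoidance latency
    and jump count, and Y-maze spontaneous alternation.  Returns group means
    and whether every effect direction matches the expected phenotype
    (control above PNE everywhere except jump count).
    """
    seeds = _child_seeds(seed, 4 * 2 * n_per_group + 3)
    models = _train_social_classifiers(seeds[-3:])
    presets = {"control": simulate.PRESETS["control"], "pne": simulate.PRESETS["pne"]}
    out: dict[str, dict[str, float]] = {g: {} for g in presets}
    idx = 0
    for g, preset in presets.items():
        ct, fol_f, fol_d, sni_f, sni_d, lat, jumps, alt = ([] for _ in range(8))
        for _ in range(n_per_group):
            s_of, s_soc, s_car, s_ym = (int(x) for x in seeds[idx : idx + 4])
            idx += 4
            of = simulate.generate_session(
                simulate.make_scenario(g, seed=s_of, duration_s=1800)
            )
            ct.append(center_time(compute_trajectory(of.tracks[0]), of.arena))

            soc = simulate.generate_session(
                simulate.make_scenario(g, seed=s_soc, n_animals=2, duration_s=600)
            )
            feats = extract_features(soc.tracks)
            fol = predict_bouts(models["following"], feats, fps=soc.fps)
            sni = predict_bouts(models["sniffing"], feats, fps=soc.fps)
            fol_f.append(fol.frequency)
            fol_d.append(fol.total_duration_s)
            sni_f.append(sni.frequency)
            sni_d.append(sni.total_duration_s)

            car = simulate.generate_car_session(s_car, preset.car_exit_hazard_per_s)
            res = score_car(compute_trajectory(car.tracks[0]), car.arena)
            lat.append(res.latency_first_jump_s)
            jumps.append(res.n_jumps)

            ym = simulate.generate_ymaze_session(s_ym, preset.ymaze_p_alternate)
            ymr = score_ymaze(compute_trajectory(ym.tracks[0]), ym.arena)
            alt.append(ymr.alternation_pct)
        out[g] = {
            "center_time_s": float(np.mean(ct)),
            "following_freq": float(np.mean(fol_f)),
            "following_duration_s": float(np.mean(fol_d)),
            "sniffing_freq": float(np.mean(sni_f)),
            "sniffing_duration_s": float(np.mean(sni_d)),
            "car_latency_s": float(np.mean(lat)),
            "car_jumps": float(np.mean(jumps)),
            "alternation_pct": float(np.mean(alt)),
        }
    con, pne = out["control"], out["pne"]
    signs = {
        "center_time_lower_in_pne": pne["center_time_s"] < con["center_time_s"],
        "following_freq_lower_in_pne": pne["following_freq"] < con["following_freq"],
        "following_duration_lower_in_pne":
            pne["following_duration_s"] < con["following_duration_s"],
        "sniffing_freq_lower_in_pne": pne["sniffing_freq"] < con["sniffing_freq"],
        "sniffing_duration_lower_in_pne":
            pne["sniffing_duration_s"] < con["sniffing_duration_s"],
        "car_latency_shorter_in_pne": pne["car_latency_s"] < con["car_latency_s"],
        "car_jumps_higher_in_pne": pne["car_jumps"] > con["car_jumps"],
        "alternation_lower_in_pne": pne["alternation_pct"] < con["alternation_pct"],
    }
    return {
        "control": con,
        "pne": pne,
        "signs": signs,
        "n_signs_matching": int(sum(signs.values())),
        "all_signs_match": bool(all(signs.values())),
    }
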