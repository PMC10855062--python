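# Methods

This note documents the models, conventions, and numerical choices behind
`mousetrek`: what each analysis computes, what the synthetic generator
emulates, and where design decisions were genuinely open.

## Position and kinematics

The animal's position on a frame is the **center of mass of its seven
tracked body parts** (nose, ears, body center, flanks, tail base): the
unweighted mean of all non-missing keypoints. A frame with no keypoint at
all has an undefined position (masked, not an error). Coordinates are
converted from pixels to cm at the trajectory boundary using a per-video
px/mm calibration carried in a sidecar configuration, never inferred from
the keypoint table itself; all public outputs are in cm and seconds.

**Travel distance** is the sum of Euclidean step lengths between sequential
valid frames. Steps spanning a missing frame are skipped rather than
interpolated — interpolation silently manufactures distance — with an
optional `bridge_gaps_s` that adds the straight-line hop across short gaps.
Time windows for binned metrics are half-open `[t, t + bin)` for dwell-time
metrics (no frame is counted twice) and closed at the end for distance, so
the step crossing a bin boundary belongs to the earlier bin and per-bin
distances sum exactly to the whole-track distance.

**Jitter inflation.** A tracker with per-keypoint jitter σ produces a
centroid that moves ~σ·√(π)/√(7) per frame even when the animal is still;
summed over a session this noise floor dominates true distance. Distance
recovery therefore supports a displacement threshold `min_step_cm`
(default 0.0, i.e. the literal frame-to-frame sum): steps below the
threshold are treated as stationary, the same device commercial trackers
use. The validation studies use 0.2 cm, about five times the centroid
jitter scale of the default observation model (0.1 cm per keypoint), which
analytically suppresses the stationary noise floor (flip probability
< 10⁻³ per frame) while passing every locomotion step (≥ 0.33 cm at
10 cm/s and 30 fps). The residual bias is the small upward inflation of
moving steps, ~4σ²_c / (2·step), under 1.5% at the default speeds.

## Tracking quality and outlier correction

The **mislabeled-frame fraction** flags a frame when any keypoint is
missing or has likelihood below a threshold. The default threshold 1.0
counts every point short of full confidence — the strictest network-quality
reading — while 0.9 is the documented practical choice for filtering
pipelines; both frame-level and point-level counts are reported, since the
two denominators answer different questions.

**RMSE** between a reference and a predicted labeling averages squared
Euclidean error over all (frame, keypoint) pairs where both sides are
present.

**Outlier correction** is body-length-relative: with L the median
nose-to-tail-base distance (median, not mean, so the artifacts being
corrected cannot corrupt the calibration), a keypoint is a *movement*
outlier when it lies more than 1.5 L from its last accepted value, and a
*location* outlier when more than 1.5 L from that frame's body center
(body center itself is corrected first, by the movement rule only). The
movement rule is not applied before a keypoint's first observation.
Outliers are replaced by the keypoint's most recent accepted value — a
causal carry-forward; replacement values are always positions the tracker
actually produced. Missing observations are filled the same way by default
and logged with reason `missing`: a dense table keeps the 7-point centroid
comparable across frames, because a change in which points are detected
moves the centroid of the remainder even when the animal has not moved.
A correction is logged only when it changes the stored value, which makes
the pass idempotent. The 1.5/1.5 criterion multipliers follow the
conventional defaults of outlier tools in this field and are configurable.

## Arena scoring

Zone membership is closed (a position exactly on a boundary is inside), so
the 20 × 20 cm center zone of the 40 × 40 cm open field has its exact area
and tie-breaking is deterministic.

**Cliff avoidance (CAR).** A jump is an on-platform → off-platform
transition whose off period persists at least `min_off_s` (default 0.5 s,
rejecting tracking flicker; the protocol itself is silent on this).
Without any jump the latency is censored at the 900 s test duration and the
count is 0. After each jump the animal is returned to the platform, so
jumps are counted per off period following an on-platform re-entry.

**Y-maze.** Four-limb arm entry is invisible to a keypoint tracker; the
documented proxy registers an entry when the body position passes 30% of
the arm length from the junction, with a junction disc (radius = arm
width) in which no arm is assigned — required so that a return to the
junction ends the current visit and a re-entry into the same arm counts
again. Spontaneous alternation is an entry (from the third onward)
differing from both of the previous two. The default percentage divides by
the **total number of entries**, the formulation used in the source
protocol; the conventional denominator (entries − 2), under which perfect
alternation scores 100%, is always reported alongside. With fewer than
three entries the percentage is undefined.

## Social metrics

The **interval distance** is the per-frame Euclidean distance between the
two animals' centroids; its empirical CDF (the accumulation curve, closed
boundary: P(X ≤ x)) summarizes a session. Two sessions are compared with
the two-sample Kolmogorov–Smirnov test. Frame-wise distances are strongly
autocorrelated, so a naive frame-level p-value is anticonservative; the
default subsamples at a stride of one second, and stride 1 reproduces the
naive frame-level procedure. For calibration studies the stride is set to
the measured correlation length of the generator (first lag where the
autocorrelation falls below 0.1, maximized over several calibration
sessions) rather than a hard-coded number. The p-value uses scipy's
automatic exact/asymptotic switch.

## Behavior classification

Features per frame cover the four standard families — all 21 pairwise
keypoint distances (cm), per-keypoint frame movements (cm), the
nose–body-center–tail-base angle (degrees), and the convex-hull area of
the seven points (cm²) — plus centered rolling means and variances over
0.2 s and 1 s windows, truncated at session edges. Two-animal sessions add
inter-animal nose/tail distances, centroid distance and its closing speed,
relative heading, and the subject's heading relative to the bearing toward
its partner.

The classifier is a random forest of 100 trees with a fixed seed —
reproducibility is prioritized over fidelity to any particular toolkit's
internals — trained per behavior label on human (or generator) frame
annotations, with a stratified held-out split reporting frame-level
precision/recall/F1. Probabilities ≥ 0.5 become positive frames; positive
runs with gaps ≤ 0.2 s are merged, runs shorter than 0.3 s dropped (all
configurable; the thresholds are conventional, the protocol is silent).
Sessions are summarized by bout frequency and total duration, the same
quantities a human scorer reports, making human–machine agreement a direct
comparison: frame-level precision/recall/F1 plus Pearson correlations of
per-session frequency and duration (undefined below three sessions).

## Stereology

Newborn neurons (BrdU/NeuN double-positive cells) are counted on every
sixth serial 40 µm coronal section. Sections anterior to bregma −2.80 mm
are dorsal dentate gyrus; a section at exactly −2.80 mm is assigned
ventral ("before" read as strictly anterior — the coordinate convention is
genuinely ambiguous, so the boundary is configurable). The per-segment
total is the scaled mean, (Σ counts / sections counted) × total sections
in the segment (defaults ≈ 45 dorsal, 30 ventral, overridable per animal),
and the whole-hippocampus value is the sum of the segments. Estimates stay
real-valued; rounding a scaled mean would bias it.

## The synthetic generator

The generator emulates the recording regime of the real assays — a
40 × 40 cm arena at 30 fps, 10–30 min sessions, one or two animals — not
any particular dataset. Its defaults are the study conditions of every
validation test.

*Latent model.* Behavior is a semi-Markov chain over locomote / rest /
groom / rear (+ follow / sniff for the subject of a two-animal session)
with geometric dwell times (means 2–8 s per state), chosen for analytic
tractability of occupancy checks. Movement is waypoint-based: straight
segments at 10–16 cm/s toward waypoints sampled inside the arena (margin
4 cm), drawn from the center zone with probability 0.35 (control). Because
the arena is convex, paths never leave it. Following re-aims at the
partner every 0.5 s and stops 4 cm short; sniffing holds the subject at
3 cm body contact; a sniff scheduled beyond 8 cm separation is executed as
a follow, and annotations always describe the executed behavior.

*Observation model.* Keypoints come from a zero-mean rigid template
(body length 6.6 cm; juveniles scaled 0.75) rotated to the heading and
deformed by state — rearing contracts the body axis to 0.55, grooming
hunches it to 0.8 and oscillates the nose at 4 Hz — then degraded with
Gaussian jitter (σ 0.1 cm per keypoint), low-likelihood frames (2%),
dropout (0.5%), and optional single-frame teleport artifacts — the point
relocates to a uniform position elsewhere in the arena at least 15 cm away,
the way a tracker glitch lands on another object in the image — whose
frame/keypoint log is ground truth for outlier-recall studies. The
zero-mean template makes the noiseless keypoint centroid coincide with the
latent position, so kinematic ground truth is exact. All randomness
derives from one seed through independent child streams per animal and
noise channel: enabling a noise channel never perturbs the latent path.

*Presets.* The control and PNE-like presets differ only in
effect-direction knobs: center-waypoint probability (0.35 vs 0.12),
groom/rear initiation (×0.5/×0.6), follow/sniff initiation (×0.5),
platform-exit hazard (0.0008 vs 0.006 s⁻¹), and Y-maze alternation bias
(0.75 vs 0.55 against a 0.5 chance floor). These encode the reported
effect *directions* of prenatal-nicotine phenotypes without claiming any
effect size.

*What it does not emulate.* Real tracker error is structured (identity
swaps, reflections, occlusion by the partner), likelihood is correlated
with pose, and real behavior has diurnal and habituation structure beyond
the bin-wise activity fall-off. Passing recovery tests on this generator
shows the pipeline arithmetic is correct under a realistic noise budget;
it does not certify performance on any specific tracker's failure modes.

## Validation studies and problem sizes

The studies in `mousetrek.benchmarks` (also behind
`scripts/acceptance.py`) use: one 30-min session for distance recovery;
one 10-min programmed-occupancy session for center time; one 10-min
session with teleport rate 10⁻³ for outlier recall; 1,000 independent
10-min two-animal session pairs (latent only) for K-S type-I calibration;
120 Poisson replicates cycling the six sampling phases for stereological
unbiasedness; and 10 simulated animals per group across all four assays —
with following/sniffing classified by a forest trained on three separate
control sessions — for the directional study. These sizes give
Monte-Carlo error comfortably below each check's tolerance while keeping a
full run in minutes on one CPU.

## Known limitations

- The four-limb arm-entry criterion is approximated by a body-position
  threshold; absolute entry counts can differ from human scoring even
  though alternation percentages are robust to the threshold.
- Carry-forward outlier replacement is causal but can freeze a keypoint
  through a long dropout while the animal moves; the movement criterion is
  then evaluated against a stale anchor.
- The K-S comparison treats strided frames as exchangeable samples;
  residual dependence beyond the measured correlation length would make
  p-values mildly anticonservative.
- The classifier contract is per-frame probabilities + bout
  post-processing; sequence models and toolkit-specific feature catalogues
  are out of scope.
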