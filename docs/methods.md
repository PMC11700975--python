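# Methods

## Scope and model

`gaitmono` implements the downstream half of a markerless gait-analysis
pipeline for Parkinson's disease (PD) screening from monocular video.
The upstream half — 2D keypoint detection and neural 2D→3D lifting —
is represented only by its *output format*: an `(F, J, 3)` array of 3D
joint coordinates in millimetres at a fixed camera rate (30 Hz by
default), covering at least the six lower-limb joints (left/right hip,
knee, ankle). Everything from that array to a clinical report is
implemented here:

1. gait-event detection (heel strike, toe-off) on keyframe conventions,
2. sixteen spatiotemporal gait parameters,
3. reliability (ICC), validity (Pearson r, differences) and
   group-difference (Kruskal–Wallis) statistics,
4. RFECV feature selection and an eight-classifier PD-vs-healthy
   evaluation,
5. a synthetic gait generator with exact ground truth, standing in for
   both the pose estimators and the clinical cohort.

## Gait parameters

Per-frame signals (all angles in radians, lengths in mm):

- knee angle `θ_i = arccos((H−K)·(A−K) / (|H−K||A−K|))`, per side;
  π is a straight leg. The arccos argument is clamped to `[−1, 1]`
  (|arg| > 1+1e−6 raises instead — that indicates broken geometry, not
  float drift).
- thigh angle: the opening angle between the two hip→knee vectors.
- step length `L_i = |A_L − A_R|`, the full 3D inter-ankle distance as
  defined; at heel strike the vertical component is near zero, so this
  matches the usual horizontal definition there.
- rates by backward differences scaled by the camera rate,
  `ω_i = f·(θ_i − θ_{i−1})`, `a_i = f·(ω_i − ω_{i−1})`; each
  differentiation shortens the series by one sample.

Events use keyframe conventions: a heel strike `F_touch` is a prominent
local maximum of the (3-frame moving-average smoothed) step-length
series — feet farthest apart at initial contact; a toe-off `F_split`
is the frame between two strikes at which the swinging ankle's vertical
coordinate peaks, the swinging side being the one with the larger
height excursion in that interval. Consecutive strikes are alternating
feet. Temporal parameters per index i, converted to seconds by
dividing frame differences by the rate f:

    single step time    (F_touch_{i+1} − F_touch_i) / f
    double support time (F_split_i − F_touch_i) / f
    single support time (F_split_{i+1} − F_touch_i) / f
    stride time         (F_touch_{i+2} − F_touch_i) / f
    double proportion   100 · double_support_i / step_i
    swing proportion    100 − double proportion

Segment values are means over the available indices (a segment holds
about two gait cycles). Two identities hold exactly in frame
arithmetic and are tested at machine precision: double + swing
proportions = 100, and `single_support_i = step_i + double_{i+1}`.

Spatial parameters are ranges of motion (max − min) of the knee-angle,
velocity and acceleration series per side, the thigh-angle velocity and
acceleration ROMs, the thigh-angle maximum, and the step-length
maximum — ten values; with the six temporal parameters, sixteen per
segment.

Division by f (not multiplication) for the temporal parameters is the
dimensionally consistent reading and reproduces the published
magnitudes (≈17 frames between strikes at 30 Hz ≈ 0.57 s); the rate
equations keep their multiply-by-f form, which is the correct finite
difference.

## Keyframe scoring (DPC-kNN)

Representative frames are scored by density-peak clustering over
k-nearest neighbours. Descriptors are the flattened joint coordinates
per frame with the per-frame centroid removed (translation invariance)
and scaled to unit RMS (so the density exponent is well conditioned for
millimetre data). Per frame:

    ρ_i = exp(−(1/k) Σ_{j∈kNN(i)} ‖x_i−x_j‖²)     (squared distances)
    δ_i = min_{j: ρ_j>ρ_i} ‖x_i−x_j‖, else max_j ‖x_i−x_j‖   (plain)

The asymmetry (squared inside the exponent, plain in the centre score)
is deliberate and matched to the source definitions. Selection ranks
γ = ρ·δ, the standard density-peak criterion; ties break to the lower
frame index; k defaults to ⌈√F⌉. An optional fusion step filters one
stream's event keyframes against a second stream's keyframes: a
candidate survives iff it is the nearest candidate within ±tolerance
(default 3 frames ≈ 100 ms) of some reference keyframe; the operation
is idempotent. Fusion is off by default in `extract_all`.

## Synthetic gait generator

The generator emulates a straight-walk capture window: ~2 gait cycles
per segment, three segments per subject, three cohorts (healthy, early
PD, mid PD), pose-estimator noise as iid Gaussian coordinate jitter
(default 3 mm — markerless estimators report joint errors of a few
mm to a few cm; 3 mm represents a good estimator at 2.8 m range).

Ankle trajectories are designed directly so that every event
convention holds in closed form, and the knee is recovered by planar
two-segment inverse kinematics (the hip–knee–ankle chain is therefore
geometrically exact, equal thigh and shank lengths):

- fore–aft ankle sweep relative to the pelvis: `x(u) = R cos(2πu)`
  per leg on the stride phase u, the legs half a stride apart, with
  `R = sqrt(step_length² − pelvis_width²)/2`. The 3D inter-ankle
  distance then peaks at exactly `step_length`, exactly at the strike
  instants, exactly one step time apart.
- ankle height: an asymmetric raised-cosine swing lift that rises
  strictly after the contralateral strike and peaks exactly at the
  toe-off instant, `double_support_fraction·step_time` after that
  strike. Its peak *is* the toe-off keyframe; its support excludes the
  strikes so it never perturbs the separation peak. The height is
  solved (Brent) so the knee-angle ROM equals `knee_rom`.
- pelvis height "vaults" at the step period with a closed-form
  amplitude that keeps the stance-leg hip–ankle distance constant to
  fourth order in phase — the stance knee holds near its strike
  flexion, as in real vaulting gait.

The ankle-height apex is placed *at* toe-off (not mid-swing) because
that is the detection convention — maximum ankle height marks the toe
leaving the ground — and it makes the double-support ratio of the
ground-truth events equal `double_support_fraction` exactly. All
events, temporal parameters, knee ROM, thigh max and step-length max
have closed-form or solver-exact truths; the velocity/acceleration ROM
truths are defined by applying the backward-difference operators at the
camera rate to the exact noiseless angle samples, because those
parameters are *defined* at the camera rate — a continuous-derivative
"truth" would differ from every 30 Hz measurement by discretization,
not by pipeline error.

Cohort presets take the published gold-standard magnitudes: healthy
step time 0.54 s, step length 553 mm, knee ROM 0.91 rad, double-support
fraction 0.222 (= 0.12 s / 0.54 s); early PD 0.56 s, 491 mm, 0.82 rad,
0.268; mid PD further scales step length by −15 % and the
double-support fraction by +30 % (a modelling choice — only box-plot
level information exists for the mid-stage group). Between-subject
SDs are the published SD columns (e.g. healthy step length 50 mm, PD
102 mm); within-subject SD is ¼ of the between-subject SD, so
test–retest reliability is high by construction (expected
ICC(2,3) ≈ 0.98 on true parameters). Draws are truncated to
physical bounds (step time 0.40–1.10 s, step length 380–900 mm,
double-support fraction 0.06–0.45, knee ROM 0.30–1.40 rad); the rare
draw outside the kinematically feasible region (short step with large
knee ROM) is nudged back (knee ROM −5 %, step +5 % per retry).

What the generator does *not* emulate: turning, gait initiation and
termination, freezing episodes, asymmetry between sides, frontal-plane
motion, foot geometry (heel vs toe markers), and temporally correlated
estimator error. Passing recovery tests therefore demonstrate
correctness of the downstream computations under the stated event
conventions — not robustness to every artefact of real video.

## Statistics

Reliability is ICC(2,k): two-way random effects, average measures,
absolute agreement, with k = 3 segments as "raters":

    ICC(2,k) = (MS_R − MS_E) / (MS_R + (MS_C − MS_E)/n)

p-values from F = MS_R/MS_E with (n−1, (n−1)(k−1)) df; the 95 % CI by
the McGraw–Wong construction for ICC(A,1) mapped to k raters by
Spearman–Brown (validated against pingouin to 1e−9 on the point
estimate and p). The consistency form ICC(3,k) is available behind a
flag. Values above 0.75 are labelled good (Koo–Li threshold). Note
the *average-measures* null is wide: at n = 50, k = 3 its sampling SD
is ≈ 0.25, so null values within ±0.5 are ordinary; the single-measures
null is about k times tighter.

Validity reports per feature and pooled group (healthy vs PD) the
means/SDs of both instruments, Pearson r with the qualitative bands
(≥0.9 very high, 0.7–0.9 high), and the difference d. The published
definition of d is ambiguous; mean absolute difference is the default
column and the signed mean is also reported. Group differences use
the tie-corrected Kruskal–Wallis H with χ² p-values, flagged at 0.05
and 0.01; no multiple-testing correction is applied, matching the
source convention of reporting raw p-values.

## Classification

Binary screening, PD (early + mid pooled) as the positive class.
RFECV with a random-forest ranker and stratified ten-fold CV accuracy
picks the subset (ties toward fewer features); the eight classifiers
(AdaBoost, DT, KNN, LDA, logistic regression, Gaussian NB, RF, SVM)
use their conventional library defaults, each inside a Pipeline with
per-training-fold standardization. Metrics are pooled over stratified
ten-fold CV predictions (accuracy, precision, recall, F1, percent);
AUC comes from leave-one-out prediction scores pooled into one ROC per
model. Folds shrink automatically (with a warning) when a class has
fewer than ten members.

Two caveats are deliberate and documented rather than hidden:

- `cohort_experiment` runs RFECV on the full table before CV, exactly
  mirroring the published workflow; at small n this selection step is
  itself optimistic (measured ≈ 60 % accuracy at zero effect with
  n = 24). The leakage *check* therefore uses `evaluate_models` with a
  fixed a-priori feature list, whose label-permutation null sits at
  chance — demonstrating the CV itself is leakage-free.
- pooled leave-one-out scores are pessimistically biased under the
  null at small n (each held-out sample faces a training set slightly
  imbalanced against its class); the null experiments use n = 60 where
  this artefact is small.

On synthetic cohorts at the published means and SDs the full-effect RF
accuracy is ≈ 80 % (range ~60–90 across seeds) — lower than the
published 93 % on the real cohort, as expected: the marginal means/SDs
alone understate the real data's separability, and the generator adds
no correlated feature structure. The workflow properties (perfect on
separable classes, chance on permuted labels, median RF accuracy
non-decreasing in effect size) are the meaningful guarantees at this
scale.

## Numerical choices and problem sizes

- Event detection defaults: smoothing window 3 frames, minimum peak
  separation 0.3 s, prominence ≥ 20 % of the series range; detected
  peaks are refined to the raw-series maximum within ±1 frame. No
  angle smoothing by default (an optional moving-average window
  exists).
- Generator feasibility margins: the strike peak of the inter-ankle
  distance must exceed any swing-phase structure by ≥ 10 %, otherwise
  the configuration is rejected — ambiguous geometry would make
  event recovery a coin flip at frame resolution.
- Test problem sizes are chosen for tight CIs at interactive runtimes:
  oracle sweeps use 100–200 random instances, reliability Monte-Carlo
  20 cohort seeds at the 59-subject scale, classification nulls 20
  seeds at n = 60, monotonicity 3 seeds × 3 effect scales at 12+12
  subjects.
- Ties: keyframe selection breaks γ ties to the lower frame index;
  RFECV score ties resolve to the smaller subset.
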