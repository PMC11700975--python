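# gaitmono

Spatiotemporal gait analysis from monocular-video 3D pose sequences,
aimed at Parkinson's disease (PD) screening in clinical movement
science. Markerless pose estimators turn a single consumer camera into
a motion-capture device; what remains between their output — per-frame
3D joint coordinates — and a clinical read-out is the part this package
implements:

- **Gait events** from keyframe conventions: heel strikes at the maxima
  of the 3D inter-ankle distance `L_i = |A_L − A_R|`, toe-offs at the
  swinging ankle's vertical apex between strikes.
- **16 gait parameters** per walking segment: six temporal (single step
  time, single/double support time, double/swing proportion, stride
  time, from frame differences divided by the camera rate f) and ten
  spatial (knee-angle ROM per side with `θ = arccos((H−K)·(A−K) /
  (|H−K||A−K|))`, velocity/acceleration ROMs via `ω_i = f·Δθ_i`,
  `a_i = f·Δω_i`, thigh-angle max, step-length max; ROM = max − min).
- **DPC-kNN keyframe scoring**: per-frame density
  `ρ_i = exp(−(1/k)Σ_{kNN}‖x_i−x_j‖²)` and centre score
  `δ_i = min_{ρ_j>ρ_i}‖x_i−x_j‖` (else the farthest distance), ranked
  by `γ = ρ·δ`, plus tolerance-window fusion of event keyframes across
  two pose streams.
- **Statistics**: test–retest reliability as ICC(2,k) from two-way
  ANOVA mean squares (with McGraw–Wong CIs), validity as Pearson r and
  mean differences against a gold standard, Kruskal–Wallis group
  comparisons.
- **Classification**: RFECV feature selection and eight classifiers
  (AdaBoost, DT, KNN, LDA, LOG, NB, RF, SVM) with stratified ten-fold
  CV metrics and leave-one-out ROC/AUC, leakage-free by construction.
- **A synthetic gait simulator** with exact ground truth (events and
  all 16 parameters) that emulates healthy / early-PD / mid-PD cohorts
  at published gait magnitudes — every downstream stage is testable
  without clinical data.

## Worked example

```python
from gaitmono import GaitParams, generate_gait, detect_events, extract_all

params = GaitParams(step_time=0.56, step_length=491.0,
                    double_support_fraction=0.268, knee_rom=0.82,
                    noise_sd=3.0, seed=7)          # early-PD magnitudes
seq, truth = generate_gait(params)                  # 3 mm pose noise
events = detect_events(seq)
print("heel strikes:", events.heel_strikes.tolist(), events.heel_strike_sides)
print("toe-offs:   ", events.toe_offs.tolist(), events.toe_off_sides)
features = extract_all(seq).features
for name in ("single_step_time", "double_support_time", "double_proportion",
             "lknee_angle_rom", "step_length_max"):
    print(f"{name:20s} {features[name]:8.3f}   (true {truth.true_features[name]:8.3f})")
```

prints

```
heel strikes: [11, 27, 44, 60, 77] ['L', 'R', 'L', 'R', 'L']
toe-offs:    [15, 32, 48, 65] ['R', 'L', 'R', 'L']
single_step_time        0.550   (true    0.560)
double_support_time     0.150   (true    0.150)
double_proportion      27.206   (true   26.800)
lknee_angle_rom         0.837   (true    0.820)
step_length_max       497.869   (true  491.000)
```

Strikes land ~16.5 frames apart (0.56 s at 30 Hz), each toe-off follows
the previous strike by the double-support interval, and every parameter
is recovered within one frame period (temporal) or ~2 % (spatial)
despite the injected pose noise. Feature tables from many segments
feed `reliability_report` (ICC per group and feature),
`validity_report` (agreement with a gold standard) and
`rfecv_select`/`evaluate_models` (PD classification).

A CLI mirrors the library:

```sh
gaitmono simulate --preset early_pd --n 10 --segments 3 --seed 42 --out sim/
gaitmono events --in sim/e000_seg0.json
gaitmono extract --in sim/e000_seg0.json --out features.csv
gaitmono reliability --features sim/ground_truth.csv --out icc.csv
gaitmono classify --features features.csv --seed 42 --out report.json
```

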