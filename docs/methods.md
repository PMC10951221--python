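# Methods

This note documents the models, numerical choices and open design
decisions behind `soleposture`. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Signal chain

**Recordings.** A recording is one foot's series of eight non-negative
zone forces with strictly increasing timestamps and a nominal rate of
50 Hz or 12 Hz (other positive rates are accepted with a warning). The
exchange format is a long CSV (one row per frame per foot) with columns
`subject_id, task, foot, time_s, f1..f8, sampling_rate_hz`; floats are
written with `%.17g` so write→read is the identity.

**Resampling.** 50 Hz recordings are brought to the 12 Hz analysis rate
in three steps: linear interpolation onto a uniform grid (absorbing
timestamp jitter, since the spectral features assume uniform sampling), a
zero-phase 8th-order Butterworth low-pass at 0.4 × target rate (4.8 Hz)
applied as second-order sections with `sosfiltfilt` (stable at this
order; zero phase avoids distorting COP dynamics), then interpolation
onto the uniform 12 Hz grid and clipping at zero. The squared (two-pass)
Butterworth response gives >40 dB attenuation for tones ≥ ~6.5 Hz; the
acceptance script measures ≈42 dB for an 8 Hz + 20 Hz mixture.

**COP.** Per frame, the force-weighted centroid of the zone coordinates.
Frames with total force below 5% of the trial's median total force are
invalid (COP undefined); they are dropped (never interpolated or
zero-filled), and every dynamic computation treats each maximal valid run
independently so that no finite difference crosses a gap. Geometry is
per-insole with ML measured from the medial edge: because the right
insole is physically mirrored, "larger ML = more lateral" holds for both
feet with no sign flip. The default geometry places the eight zones at
anatomically plausible positions on a 100 × 250 mm footprint; the vendor
publishes no coordinates, so the geometry is configurable.

**One-foot stance.** The trial is segmented into left-support frames
(left loaded, right not) and right-support frames, at 10% of each foot's
maximum total force (a trial-median threshold would be distorted by the
unloaded half). Brief ground touches of the lifted foot split segments;
segments shorter than 0.25 s are discarded. Only the weight-bearing
foot's frames enter the feature bank: the left-stance segments produce
the "left" vector and the right-stance segments the "right" vector, and
the average/asymmetry combination then compares the two stances.

## Feature bank (19 + 21 + 20 = 60 per foot)

The canonical inventory follows the classical stabilometry literature
(time-domain position/dispersion measures, displacement dynamics, Welch
spectra) plus the sway-density family. Notable conventions:

- **95% confidence ellipse**: area = π · χ²₀.₉₅(2) · √(λ₁λ₂) with λ the
  eigenvalues of the sample covariance (ddof = 1); semi-axes
  √(χ² λ); orientation is the major-axis angle in (−90°, 90°], set to 0
  for isotropic/degenerate clouds so constant trajectories keep all 19
  positional features defined.
- **Amplitude ratio ML/AP** = range ML / range AP; a single point (both
  ranges zero) is defined as 1.
- **Velocities** are central differences (`np.gradient`) at the sampling
  rate, per valid run. Zero crossings count sign changes of the velocity
  after discarding exact zeros, so a constant trajectory has 0.
- **Swept area per second**: sum of per-step triangle areas around the
  run mean, divided by the valid duration (for a circle of radius r at
  rotation frequency f this converges to π r² f).
- **Hybrid mean frequencies**: mean velocity / (2π · mean distance)
  (resultant) and mean |v| / (4 · mean |deviation|) per axis — the
  oscillation frequency of a sinusoid with the same mean displacement and
  velocity.
- **Sway density**: for each instant, the time (s) spent by consecutive
  samples inside a 3 mm circle around the current point; the curve is
  smoothed with a 0.5 s moving average before peak picking (the radius is
  standard; smoothing window and peak rule are this package's documented
  defaults). Features: mean peak value, mean spatial distance and mean
  time between successive peaks.
- **Spectra**: Welch PSD, Hann window, `nperseg = min(128, N/2)`, 50%
  overlap, linear detrend. The PSD uses the concatenation of valid
  samples: tasks with intermittent loading (gait) would otherwise never
  accumulate a window, and the join artefacts are broadband and small
  next to the sway bands. Band energies (<0.5, 0.5–2, >2 Hz) are
  fractions of total power, computed from the cumulative spectrum
  interpolated at the exact band edges so a peak straddling an edge is
  split, not dropped. A constant signal reports total power 0 and NaN
  for all other spectral statistics.

Undefined values are always NaN (explicit missing), never silent zeros.
Degenerate limits that have analytic values (zero crossings of a constant
trajectory, zero ellipse area) are reported as those values.

**Combination.** Average = (L+R)/2; asymmetry = |L−R|/(L+R), with 0/0
defined as 0 and a zero denominator with unequal sides as NaN. For signed
features (e.g. the ML mean about an arbitrary origin) the denominator can
be negative; the value is computed exactly as the formula states but a
warning flags that it then falls outside [0, 1].

**Table.** 120 columns per task (60 average + 60 asymmetric), 720 over
six tasks, indexed by a (cop_type, task, feature) column hierarchy.
Missing tasks/feet yield NaN blocks with warnings; imputation is by
column median (configurable). Min-max normalization maps each column to
[0, 1] using, by default, all subjects (the single global scaling the
original workflow suggests); a fit-rows argument supports per-fold
scaling, and values outside the fit range are not clipped by default.

## Synthetic cohorts

Group effects are injected in **latent COP space**, not feature space, so
all 60 features respond coherently, the way physiology would. Static sway
is a stationary band-limited (<3 Hz) Gaussian process per axis built from
three unit-SD components (<0.4 Hz, 0.4–1.5 Hz, 1.5–3 Hz) mixed as
`low_band_gain·slow + mid + 0.6·zero_crossing_gain·fast`, renormalized to
unit SD and scaled by the sway SD — so the SD parameter controls
amplitude while the gains shift spectral content (the low-band gain acts
on ML only; the zero-crossing gain raises the velocity sign-change rate
on both axes). Active tasks add deterministic templates: a raised-cosine
AP reach-and-return (FR, 55 mm), a deeper excursion with a 35% load dip
(BO, 60 mm), and alternating 0.6 s single-support stances with a
heel-to-toe AP sweep and a double-bump load curve (GAIT; swing frames
carry zero force). One-foot stance loads the left foot for the first half
of the trial and the right for the second. Default durations: 30 s quiet
stance, 60 s one-foot, 20 s gait, 15 s reach, 10 s bend; baseline load
700 N per loaded foot around a rest COP of (50, 130) mm.

The right foot scales the left's offsets and sway SDs by the task's
`asymmetry_gain` while **sharing the same latent noise realisation**, so
a gain of exactly 1 produces mirror-identical feet and asymmetry features
that vanish to rendering precision — which is what makes the gain
interpretable. Per-subject heterogeneity is mild jitter on the task
parameters (±0.4 mm on offsets, ×lognormal(0, 0.1) on SDs).

**Rendering.** Each latent (COP, total force) frame becomes eight
non-negative zone forces by minimum-norm constrained least squares:
min ‖f‖² s.t. Σf = F, Σf·D = F·COP, f ≥ 0. The unconstrained minimum-norm
solution is computed in closed form for all frames at once; the few
frames where it has negative components fall back to a small active-set
solve. COP targets outside the zone hull are projected onto the hull
boundary with a warning. Round-trip error (render → recompute COP) is
~1e-13 mm and force conservation is exact to round-off.

**Presets.** `pd_vs_control` injects an EO lateral shift (+4 mm), larger
EO/BO sway (×1.3–1.4) and EO/BO asymmetry gains (×1.15);
`faller_vs_nonfaller` injects faster EC sway reversals (zero-crossing
gain ×1.8), more ML low-band power during gait (×2.5) and EC asymmetry
(×1.2) — directions follow the contrasts the feature families are meant
to capture; magnitudes are free parameters of the generator, scaled by
`effect_scale`. `single_ml_offset_preset` plants one dominant effect
(+10 mm EO ML offset against 2 mm sway, d = 5) for recovery experiments.

## Selection, evaluation, interpretation

- **Pre-filter**: per-feature one-way ANOVA F (`sklearn.f_classif`),
  keep p ≤ 0.05. A perfectly separating feature (F = ∞, p = 0) is kept;
  a feature with no variance at all (F undefined) is skipped. The filter
  prunes the search space; it makes no significance claim.
- **SFS**: greedy forward path over the survivors; at each step the
  feature maximizing stratified 5-fold CV F1 of the architecture's
  default-hyperparameter model is appended (ties keep the earliest
  column). The optimal subset is the shortest prefix attaining the
  maximal CV F1. The full path is the default; a `max_features` cap
  exists for scaled-down experiments. Tuning (exhaustive grid by CV F1 on
  the fixed subset, first-best tie rule) happens after the subset is
  fixed, matching the stated order of the original workflow. Default
  grids: SVM C∈{0.1,1,10}×{linear,rbf}; RF {100,300} trees × depth
  {None,5}; LR C∈{0.1,1,10}; KNN k∈{3,5,7,9}×{uniform,distance}; GNB
  var_smoothing∈{1e-9,1e-7}. KNN neighbor counts are clamped to the
  training-fold size where necessary.
- **Evaluation**: the same seeded stratified fold partition is reused
  across the five architectures so comparisons are paired. Per fold:
  accuracy, precision, recall, F1, Cohen's κ, AUC; ROC curves are
  vertically averaged on a 101-point FPR grid; AUC is reported as
  mean ± SEM over folds; out-of-fold predictions are retained. The
  positive class is the lexicographically larger label.
- **Leakage modes.** `paper_faithful` (default) fits normalization, the
  pre-filter and SFS once on all subjects, then cross-validates — the
  single global scaling the original workflow implies. This is
  optimistic on small cohorts: on 120-feature null cohorts with 16
  subjects the acceptance script measures mean AUC ≈ 0.8 despite no
  signal. `leakage_safe` is a true nested CV: scaling, pre-filter and
  SFS are refit inside each training fold and the test fold is touched
  only for prediction; on the same null cohorts it sits at chance.
  Both numbers are reported so the optimism is visible rather than
  hidden.
- **Task-set comparison**: fold-level metrics are modelled by OLS with
  task set and architecture as fixed effects (architecture blocks the
  paired design; the original description of a mixed model never names
  its random effect, so the fixed-effects block design is used), with
  the Bonferroni threshold 0.05/3 ≈ 0.017 for the three pairwise
  comparisons.
- **Shapley values**: interventional expectation over a background set
  (each fold's training rows; the explained output is the positive-class
  probability when available, else the decision value). Subsets up to 16
  features are enumerated exactly — local accuracy, symmetry and the
  null-player axiom then hold to round-off, and a linear decision
  function reproduces φ_j = w_j(x_j − E[x_j]) exactly; larger subsets
  use seeded permutation sampling. "Top Shapley feature" = highest mean
  |φ| pooled over all folds' test rows (the aggregation is not uniquely
  pinned down by the original description; mean |φ| is the common
  choice).
- **Common / key features**: common = selected by ≥3 of the 5 optimal
  subsets; key = names that are, within some task-set analysis, both
  common and some model's top Shapley feature, deduplicated across task
  sets. Misclassified subjects: wrong out-of-fold under ≥3 of 5
  architectures. Group z-scores standardize against the pooled mean/SD
  (ddof = 1) so that balanced two-group scores are opposite-signed.

## Problem sizes and determinism

Tests and the acceptance script run scaled-down experiments chosen as
realistic smallest cases for each property: recovery experiments use the
EO task only with 8+8 subjects, a 4-step SFS cap and 20 seeds; null-chance
checks use three seeds and the three fast architectures; structural checks
use a 2+2 cohort over all six tasks. Every stochastic step is seeded
(cohorts via `SeedSequence` spawning, folds via the experiment seed), and
a repeated experiment with the same seed serializes to byte-identical
JSON.

## What the synthetic generator does and does not show

The generator emulates group-dependent stationary sway statistics,
task templates, gait loading, left/right asymmetry and the 50 Hz→12 Hz
acquisition chain. It does not model foot-shape/pressure-image detail,
non-stationary fatigue or attention effects, sensor drift/noise floors,
or the correlated multi-feature physiology of real Parkinsonian sway
beyond what the injected latent effects induce. Passing recovery tests
therefore demonstrates that the pipeline finds effects of the stated size
and shape under its own assumptions — not that real cohorts would yield
the same feature sets or AUCs.

## Known limitations

- Feature formulas follow the classical stabilometry definitions named
  above; where a printed inventory gives only feature names, the exact
  formula is this package's documented choice and is config-replaceable.
- The asymmetry ratio loses its [0, 1] interpretation for signed
  features (flagged at computation time).
- `grid_tune` tunes on the same folds used by SFS (as the original order
  implies); fully unbiased tuning would nest another CV level.
- The external-data adapter is limited to the documented CSV dialect;
  vendor binary formats are out of scope.
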