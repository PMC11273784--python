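# Methods

## Problem setting

An intracranial aneurysm (IA) is a focal bulge of a cerebral artery wall;
predicting which aneurysms will rupture is a long-standing clinical problem.
Two families of predictors dominate the literature: morphometric indices
(aspect ratio AR, size ratio SR, surface-to-volume ratio S/V, daughter sacs,
growth location) and hemodynamic indices derived from computational fluid
dynamics (wall shear stress WSS, oscillatory shear index OSI, low-shear area
LSA, impingement-zone concentration, qualitative flow-pattern judgments).
This package studies a third ingredient: fixed-length *learned* features of
the attributed surface point cloud itself ("hemodynamic cloud features"),
obtained with a PointNet-style permutation-invariant network, and asks whether
appending them to the tabular features changes cross-validated classification
of rupture status.

Because clinical DSA/CFD data cannot be redistributed, the package ships a
synthetic cohort generator that plays the role of the imaging + CFD stages.
Everything downstream of the generator (morphometry, wall-field statistics,
feature extraction, benchmarking) treats its input as opaque data and works
unchanged on real clouds supplied in the same CSV/STL formats.

## Synthetic cohort generator

`EffectConfig` fixes the study conditions; the whole cohort is a pure function
of the config, including its seed.

**Geometry.**  Each sac is an ellipsoid with semi-axes (a, b, c) truncated
below the equator where its cross-section shrinks back to the neck radius,
capped by an explicit neck plane (normal pointing at the dome) and joined to
an open parent-vessel tube.  Sac radii are lognormal (median ≈ 2.9 mm,
log-sd 0.12); the dome axis c carries the label effect: ruptured cases add
+0.35 to the log-elongation (≈ 42 % longer sacs), driving AR upward, and their
neck fraction drops by 0.06.  The parent diameter is N(3.5, 0.35²) mm.  These
magnitudes were chosen once to give overlapping but clearly shifted AR
distributions of the kind reported for ruptured vs unruptured aneurysms
(AR ≳ 1.6 flagged as high risk); they are configuration, not constants.

**Wall fields.**  Spatial correlation comes from radial-basis mixing: a
standardised field is a weighted sum of Gaussian bumps at 12 random surface
points with length-scale 0.8 × the sac RMS radius.  log-WSS = 1.4 (≈ 4 Pa)
+ label shift (−0.6 for ruptured) + 0.35 × field, times a multiplicative
low-WSS patch whose footprint covers 8 % of the sac area (+20 points for
ruptured).  OSI = 0.5 · logistic(−2.5 + 1.2·label + field), clipped to
[0, 0.5].  Pressure is a 13 kPa baseline plus a 40 Pa/mm linear trend along a
random direction plus smooth noise.  Velocity is a lognormal near-wall speed
proxy (≈ 0.2 m/s): wall velocity is zero under no-slip, so this attribute is
deliberately a free smooth field and should not be interpreted physically.
Qualitative flags are label-conditional Bernoulli draws (e.g. P(complex flow)
= 0.30 vs 0.72).  `EffectConfig.null()` zeroes every label-linked difference,
giving signal-free cohorts for null calibration.

**Sampling.**  Clouds contain 3000 points drawn area-uniformly on the sac
lateral surface (face chosen ∝ area, uniform barycentric point inside), each
with weight = sac area / 3000 so that area fractions are weighted sums.

**What the generator does *not* emulate:** real vascular-tree context, lumen
irregularity and blebs, CFD boundary-layer structure, inter-feature
correlations of clinical cohorts, measurement noise of manual morphometry.
Passing tests therefore demonstrate the correctness and statistical sanity of
the pipeline, not clinical performance.

## Morphometry

All indices are computed against the annotated neck plane: height is the
maximum signed vertex distance; neck width is the maximal pairwise distance
among intersections of sac edges with the plane (the "maximal section
diameter" convention, reproducible where manual width measurements are not);
area is the triangle-area sum of the sac lateral surface; volume closes the
sac at the neck section (fan triangulation when no cap faces exist) and
applies the divergence theorem.  AR = height/neck width and SR =
height/parent diameter follow the standard literature definitions.  Plane
tolerances are relative at 1e-6, matching both the vertex-merge tolerance and
STL single precision.  Region labels are {sac, neck_cap, parent_vessel}; the
cap participates in the volume integral but never in area or sampling.

## Wall-field statistics

Summaries are max/mean/min per attribute, area-weighted means when weights are
present (for area-uniform synthetic clouds the two coincide).  Thresholds are
deliberate configuration because the literature fixes none: LSA defaults to
WSS < 10 % of the cloud mean WSS, HOA to OSI > 0.01, the impingement zone to
WSS ≥ 0.8 × max (inclusive, so a uniform field has fraction 1) with
concentration flag 1 when the fraction is below 0.5.  All three fractions are
monotone in their thresholds.  OSI from time-resolved shear vectors uses the
standard definition OSI = ½(1 − ‖∫τ dt‖/∫‖τ‖ dt) with trapezoidal
integration, clipped to [0, 0.5] after a 1e-12 tolerance; the all-zero series
is defined as 0 with a warning.  The four qualitative indicators are
streamline-level visual judgments in practice; the package treats them as
input annotations (drawn by the generator) and validates them as strict
{0, 1} codes rather than attempting streamline computation.

## The cloud-feature extractor

Architecture (channels C1 ≤ C2, C3 ≤ C4): sample 1024 points (without
replacement when the cloud is larger), centre coordinates at the centroid and
z-score the four physical attributes per cloud (units are heterogeneous — Pa
vs m/s — and unnormalised scales dominate the shared MLP); an input T-Net
predicts a 3×3 transform applied to coordinates only, since spatial pose is
what alignment should address and "rotating" WSS values is meaningless (a 7×7
variant remains available via `input_transform_mode="full"`); shared MLP
7 → C1 → C2 (affine + batch norm + ReLU per point); a feature T-Net predicts a
C2×C2 transform with orthogonality penalty ‖AAᵀ − I‖²_F; shared MLP
C2 → C3 → C4; coordinate-wise max over points yields the 1×C4 global feature.
T-Net hidden widths scale with the channel config and their output layers are
zero-initialised with identity bias, so both transforms start as exact
identities.

Training is supervised: a two-layer head (C4 → max(8, C4/2) → 2) maps the
global feature to rupture logits; the loss is mean cross-entropy + 1e-3 ×
orthogonality penalty, minimised with Adam (lr 0.01, batch 32, 20 epochs by
default).  The head stays on the returned network but extraction ignores it.
Point samples are drawn once per cloud per training run and held fixed across
epochs.  Batch norm uses batch statistics during training and frozen running
statistics during extraction, so features are deterministic; with fixed
weights and a fixed sample the global feature is bit-identical under any
permutation of the input points.  The network runs in float32 on a hand-rolled
reverse-mode autodiff core (`hemocloud.autodiff`) whose primitives are
finite-difference checked in the test suite.

**Leakage control.**  Within cross-validation the extractor is trained on the
training folds of each split only and then embeds every case of that split;
training it once on all data would leak test labels into the features and
inflate AUC.

## Benchmarking

Feature groups: A = geometry block + hemodynamics block (flags enter as
numeric 0/1 columns); B1/B2/B3/B4 append 1024/64/32/16-d cloud features from
the corresponding channel preset.  Normalisation is per-fold z-scoring with
training statistics; constant columns map to zero.  Folds are stratified
(shuffled, seeded) because the default 40/149 imbalance makes unstratified
10-fold fragile; fold count must not exceed the minority count.  Out-of-fold
scores are pooled and metrics computed once: accuracy/sensitivity/specificity
at a fixed 0.5 threshold (positive class = ruptured), AUC by trapezoidal
integration of the tie-grouped ROC polygon (equivalent to the midrank
Mann–Whitney statistic, which the tests verify pairwise).  Classifiers use
library defaults with fixed seeds and single-threaded fits: XGBoost, LightGBM,
scikit-learn histogram gradient boosting, an RBF-kernel SVM with Platt-style
sigmoid calibration for probability scores, and logistic regression.

## Numerical choices and degenerate inputs

* Vertex merging on STL read snaps coordinates to a 1e-6 mm grid; zero-area
  facets are reported with their indices.
* The volume integral requires a closed region and warns on inconsistent
  winding; the absolute value is returned so orientation conventions cannot
  flip signs.
* Area fractions are clipped to [0, 1] against float round-off of normalised
  weights.
* A neck radius ≥ the smaller equatorial semi-axis is a degenerate geometry
  and rejected; empty sac regions, single-class training sets, non-binary
  flags and OSI outside [0, 0.5] raise validation errors naming the offender.
* Max-pool gradients split equally among tied points.

## Problem sizes used by the shipped tests and script

The test suite exercises cohorts of 20–60 cases and the acceptance script the
full 149-case default cohort with 12 training epochs per fold — sizes chosen
so the whole pipeline, including ten per-fold extractor trainings, completes
in minutes on a single CPU while leaving every structural contract (3000-point
clouds, 1024 input points, 109 + 40 cases, the four feature dimensions) at its
full default value.

## Known limitations

* The generator's label effects are strong enough that the default cohort is
  nearly separable from tabular features alone; cloud features therefore add
  headroom only in harder configurations (smaller effects, fewer cases).
* "Velocity" on a no-slip wall is a proxy attribute, not physics.
* No hyperparameter search, calibration analysis, AUC confidence intervals or
  external validation; fluid–structure interaction and streamline analysis
  are out of scope.
* Binary STL stores float32; round-tripped meshes agree with their source to
  single precision only, which bounds morphometry reproducibility at ~1e-6
  relative.
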