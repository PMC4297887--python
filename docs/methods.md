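# Methods

`cispredict` re-implements, as a tested pipeline, a single-patient
protocol for predicting conversion from a clinically isolated syndrome
(CIS) to clinically definite multiple sclerosis (CDMS) within a 1- or
3-year follow-up, from a baseline brain scan and clinical record.  This
note documents the model, the synthetic data that stands in for the
(non-depositable) patient cohort, the numerical conventions, and what the
package's tests do and do not demonstrate.

## The prediction problem

Each patient contributes twelve features spanning fourteen numeric
dimensions:

| feature | dims | space | definition |
|---|---|---|---|
| age | 1 | — | years at baseline |
| gender | 1 | — | 1 male, 0 female |
| cis_type | 1 | — | 1 optic neuritis, 2 spinal cord, 3 brainstem, 4 other |
| edss | 1 | — | EDSS at baseline, raw (0–10 in 0.5 steps) |
| lesion_count | 1 | native | number of 18-connected components of the lesion mask |
| lesion_load | 1 | native | lesional voxels |
| mean_pd, mean_t2 | 2 | native | mean PD / T2 intensity over lesional voxels |
| mean_dist_center | 1 | template | mean distance (mm) of lesional voxels to the centre voxel |
| central_cube | 1 | template | any lesional voxel inside the closed 1 cm³ cube at the centre |
| min_axis_dist | 1 | template | min over components of the in-plane distance (mm) of the component centroid to the vertical axis |
| size_profile | 3 | native | component counts in bins 1–15 / 16–36 / 37+ voxels |

The label is +1 (converter: second clinical attack within the horizon)
or −1 (non-converter).  The classifier is a soft-margin SVM with
polynomial kernel K(**x**, **y**) = (**x**ᵀ**y** + c)^d, d ∈ {1..5},
fitted by SMO.  Evaluation and selection follow the small-cohort
protocol:

1. **Balanced subsampling.**  The majority class is subsampled without
   replacement to the minority size (22+22 = 44 at 1 year, 31+31 = 62 at
   3 years), removing the hyperplane bias of imbalanced training.
2. **Leave-one-out CV.**  Train on n−1, classify the held-out patient,
   rotate; confusion counts are aggregated over the n folds and turned
   into accuracy, sensitivity, specificity, PPV and NPV (percent;
   zero-denominator ratios are NaN, never 0).
3. **Bootstrap summary.**  Steps 1–2 repeat over B balanced cohorts
   (default 100); each metric is reported as mean, 95 % percentile CI
   (2.5th/97.5th of the B values) and min–max range.
4. **Selection.**  Forward (greedy) search grows the feature set one
   feature at a time by best mean bootstrap accuracy, each candidate
   subset represented by its best degree, stopping when accuracy no
   longer increases (non-strict).  Exhaustive search scores all 2^k
   subsets (4096 for k = 12, the empty set counted but not evaluated).
   All candidates share the same bootstrap seed stream, so comparisons
   are paired and the exhaustive optimum can never score below the
   forward result.

### Fixed conventions

Where the protocol leaves details open, the package fixes them once:

- **Kernel constants** c = 1, C = 1 (the defaults of the MATLAB
  trainer the original protocol names), solver cap 10⁷ iterations;
  non-convergent folds are counted and reported, never dropped silently.
- **Standardisation** to zero mean / unit variance is computed from the
  training rows of each fold only and applied to the held-out point;
  zero-variance columns keep scale 1.  It can be switched off.
- **Tie rule**: a decision value of exactly 0 predicts non-converter
  (the conservative call).
- **Selection tie-breaks**: lower degree, then smaller subset, then
  lexicographic position in the canonical feature order.
- **Brain centre** = the voxel at index (⌊nx/2⌋, ⌊ny/2⌋, ⌊nz/2⌋) of the
  template lattice; all distances are in mm via the per-axis voxel
  sizes (index distances would be wrong on anisotropic lattices).
  The vertical axis is the inferior–superior line through that voxel;
  the central cube is the closed box |Δ| ≤ 5 mm per axis.
- **Component labelling** is deterministic (first-seen raster order);
  empty lesion masks are a hard error everywhere (inclusion requires at
  least one lesion).
- The 21-vs-22 within-fold imbalance inherent to LOO on a balanced
  cohort is accepted unweighted; it affects both classes symmetrically.

## Synthetic cohorts

No patient scans are distributable, so the package ships a generator
whose defaults encode the published study conditions:

- **Cohort sizes**: 22/52 (1 year) and 31/39 (3 years).
- **Lesion counts**: zero-truncated negative binomial, r = 0.983,
  mean = 13.98, calibrated numerically so the proportions of patients
  with ≤3 / 4–10 / >10 lesions match the published 14/74, 23/74, 37/74
  (fit error < 10⁻³ per bin).
- **Lesion sizes**: geometric, p = 0.027, truncated at 200 voxels; the
  three size-profile bins then hold 34 / 29 / 37 % of lesions.
- **Shape and placement**: face-adjacent random-walk blobs (exactly
  18-connected by construction), placed on a periventricular in-plane
  ring (75 %) or uniformly in an ellipsoidal brain support (25 %).
  Each lesion grows only into unoccupied voxels and is surrounded by an
  18-dilated one-voxel shell, so distinct lesions remain distinct
  components.
- **Intensities**: background ≈ N(100, noise_sd), air ≈ N(5, ·),
  lesions N(100 + contrast, noise_sd) with contrast 30 on both PD and
  T2 (hyperintense).  No intensity statistics were published; the
  contrast is an arbitrary, configurable choice.
- **Template mask**: the native lesion voxels pushed through a fixed
  per-axis scale-and-shift affine about the lattice centres.
  Deformable registration is deliberately not emulated: the template
  mask exists to exercise the distance features, not to be anatomical.
- **Clinical fields**: age ≈ N(34, 7.5); P(male) = 25/74; presentation
  probabilities 0.86/0.06/0.07/0.01 (optic/spinal/brainstem/other);
  EDSS from a rounded gamma with median ≈ 1 — all anchored to the
  published cohort table.
- **Reproducibility**: each patient is drawn from a counter-derived
  substream of the master seed (`SeedSequence(seed, spawn_key=(i,))`),
  so cohorts are bit-identical across runs and independent of
  generation order.

**Planted effects** are standardised class-mean shifts (converters minus
non-converters) applied per feature: higher lesion load, shorter
distances to the vertical axis and brain centre, younger age, fewer
males, more spinal-cord presentations — the directions reported for
converters.  Count and load shifts are solved in SD units against the
generator's own (truncated) distributions; load shifts realise ≈ 0.7 of
the nominal SD on coarse lattices because blobs can be trapped by the
boundary or by placement saturation.  Distance and probability effects
(radial placement scaling, category-probability boosts) are monotone in
the requested effect size but not exactly SD-calibrated.  The
monotonicity is what the tests rely on.

**What the generator does not emulate**: MRI physics (bias fields,
partial volume, noise correlations), anatomy beyond an ellipsoid,
deformable registration, inter-rater mask variability.  Passing tests
therefore demonstrate that the *pipeline machinery* is correct and
well-calibrated, not that any particular accuracy is attainable on real
patients; the published headline accuracies (71.4 % / 68 %) depend on
the unreleased scans and are not reproduction targets.

A second, feature-level generator draws Gaussian design matrices with
planted mean shifts directly.  Simulations about the classifier and the
selection logic ("one informative feature among pure noise", XOR
interactions, nulls) use it, because image-level features cannot be made
pure noise individually.

## Numerical and statistical notes

- **SVM backend.**  Fits go through scikit-learn's libsvm bindings
  directly rather than the `SVC` wrapper: the evaluation protocol
  performs ~10³ solver fits per bootstrap summary on ~43-row problems,
  where the wrapper's per-fit validation overhead is ~30× the solve
  time.  Decision values are cross-checked against `SVC` in the tests.
- **LOO null bias.**  On a balanced cohort with uninformative features,
  LOO is *anti-calibrated*: the held-out patient's class is always the
  training minority, so near-chance classifiers drift below 50 %
  accuracy.  The effect is dramatic for a single noise feature at
  degree 1 (≈ 26 %) and mild for the full 12-feature set at degree 2
  (≈ 47 %).  The package's null-calibration checks use the full feature
  set at degree 2, where the protocol operates; the bias itself is a
  property of the protocol, faithfully reproduced.
- **Winner's curse.**  Accuracies of *selected* subsets are optimistic
  (selection and evaluation share the same bootstraps, as in the
  original protocol); exhaustive search amplifies this across 4095
  models and its reports carry an explicit warning.  No correction is
  applied, matching the protocol.
- **Problem sizes.**  Simulation-heavy tests and the acceptance script
  run the image pipeline on a reduced lattice (64×64×24 native at
  3×3×5 mm; 45×54×45 template at 4 mm) and Monte-Carlo loops at B = 20,
  degrees {1, 2}, 100 replicates; the generator's defaults remain the
  full-resolution lattices (256×256×46 at 0.9375×0.9375×3 mm;
  91×109×91 at 2 mm).  Full-scale runs (B = 100, degrees 1–5, forward
  selection over all 12 features) are a few CPU-minutes.

## Known limitations

- The CIS-type code enters as a single ordinal column (as in the
  original protocol, which notes the coding is arbitrary and its
  permutation changes accuracies by ≤ 1.7 %); `cispredict select
  --permute-cis-coding` reproduces that robustness check, without a
  numeric target.
- `balanced_subsample` requires both classes non-empty and LOO folds
  must retain both classes; degenerate cohorts raise rather than
  silently degrade.
- The generator's planted distance effects shrink placement radii, which
  on small lattices also perturbs crowding (and hence realised load and
  count) slightly; effect sizes should be read as monotone knobs, exact
  only for the clinical Gaussian shifts and the count/load means.
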