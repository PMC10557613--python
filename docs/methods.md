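# Methods

## Setting and data model

The package analyzes regional morphometrics of one hemisphere per patient
(the hemisphere preserved after epilepsy surgery) against the matching
hemisphere of controls, and the two patient groups (preserved-LH vs
preserved-RH) against each other. The in-memory containers are plain pandas
DataFrames: a long-format table with one row per
(subject, hemisphere, region, measure) cell, and a metadata frame with
group, age, gender, scanner, preserved hemisphere, procedure, and binned
ILAE seizure outcome. The cortical vocabulary is the 34-region
Desikan–Killiany parcellation. The subcortical vocabulary defaults to nine
structures (thalamus, caudate, putamen, pallidum, hippocampus, amygdala,
accumbens, ventral DC, cerebellum cortex); the exact nine are configurable
because published ROI selections vary, and only five of ours are certain to
match any given study's set — the other four are a reasonable FreeSurfer
default, not a canon.

Missing cells are permitted and handled by listwise deletion within each
analysis block. Gender enters every design matrix as a 0/1 indicator with
F = 0, M = 1; the reference level is arbitrary but fixed.

## Preprocessing

**Harmonization.** Per region-measure (features of one hemisphere block),
values are modelled by least squares as

    x = b0 + b1*group + b2*age + b3*gender + c_s + delta_s * e

with scanner indicator columns (first scanner = reference, c_ref = 0).
`c_s` is the additive scanner effect; `delta_s` is the within-scanner
residual SD divided by the pooled residual SD. The transform subtracts
`c_s`, rescales residuals by `1/delta_s`, and re-adds the covariate
structure, so group/age/gender effects survive harmonization. Scanner is in
the design deliberately: with scanner assignment correlated with group (as
in realistic cohorts), estimating the additive effect from residual means
of a scanner-free fit lets part of the scanner shift be absorbed into the
group coefficient. A single-scanner fit reduces to the identity transform.
No empirical-Bayes shrinkage is applied to the per-scanner parameters:
estimates are plain location/scale, which keeps the model transparent at
the cost of extra variance with few subjects per scanner.

**Winsorization.** Per (group, hemisphere, region, measure) stratum —
patients pooled across preserved-hemisphere subgroups, controls separate —
values outside the 5th–95th percentiles are replaced by the percentile
values. Percentiles use linear interpolation between order statistics
(NumPy's default, the "type 7" convention); re-applying a fitted transform
is idempotent. An option winsorizes LH- and RH-preserved patients as
separate strata.

**Normalization.** Cortical surface area is divided by the mean regional
area of that subject-hemisphere (the normalized values average exactly 1);
cortical volume becomes a percentage of hemisphere total GM + WM + LV;
thickness is never normalized. The pipeline default order is harmonize →
winsorize → normalize, configurable because no single order is canonical.

## Univariate inference

For each ROI, an OLS model `y = b0 + b_group*group + b_age*age +
b_gender*gender + e` is fit and the group coefficient is the test
statistic. The null distribution comes from shuffling the group labels
(covariate rows stay attached to subjects — raw-data permutation, not
residual permutation) and refitting; the default p-value is the strictly-
exceeding fraction `#{|b_perm| > |b_obs|}/n_perm` with `n_perm = 1000`. A
smoothed estimator `(#exceed + 1)/(n_perm + 1)` is available; it can never
return 0 and is the safer choice when calibration matters.

Numerical details of the permutation engine:

* The group coefficient for all shuffles is computed with the
  Frisch–Waugh–Lovell identity, `b = (g'My)/(g'Mg)` with `M` the projector
  orthogonal to intercept+covariates, so 1,000 shuffles cost two matrix
  products. A unit test pins exact agreement with the plain OLS solve.
* Exceedance uses an epsilon guard (1e-9 relative): relabelings whose |b|
  equals |b_obs| in exact arithmetic (the identity and the label-swapped
  complement) must not count as exceedances, and without the guard float
  noise decides those comparisons by coin flip — visible as a ~1/70 bias at
  n=8 against exhaustive enumeration.
* A shuffled indicator that is exactly collinear with the covariates (or a
  constant-y limit) has no identifiable group effect; its coefficient is
  taken as 0.
* Each region-measure draws from its own random substream spawned from the
  run seed, so results are independent of region order and of which regions
  are present, and parallel execution stays reproducible.

Benjamini–Hochberg correction (statsmodels' step-up implementation,
verified against a hand-rolled textbook oracle) is applied across the ROIs
of one measure family within one contrast. Evidence for the null is
reported as `BF01 = exp((BIC_alt - BIC_null)/2)` from the two Gaussian
OLS fits differing only in the group column; equal residual sums of squares
give `BF01 = sqrt(n)` exactly. The BIC approximation needs no prior choice;
absolute BF values under other priors (e.g. JZS) will differ, so BF01 is an
evidence summary, not a prior-free constant.

## Multivariate stage

Forward binary logistic regression predicts group membership (or the
high/low ILAE bin, patients only) from ROI candidates. The base fitter is
Newton/IRLS with an iteration cap of 100 and linear predictors clipped at
±30; (quasi-)separation — a real risk at n as small as 13 vs 51 — is
detected from pinned fitted log-odds or drifting coefficients and flagged
on the selection path instead of being silently reported, and selection
stops there because R² is saturated. Entry uses the likelihood-ratio
chi-square (1 df) against the current model with entry threshold p < .05; a
Rao score-test option is provided for parity with packages that enter by
score test. Selection also stops when the Nagelkerke R² gain falls below
.001. Ties in entry p break by larger R² gain, then lexicographic name, so
selection is deterministic and order-invariant. Candidates collinear with
the current model are skipped (a duplicate of an entered predictor can
never enter).

Nagelkerke R² is `(1 - exp(2(ll0 - ll1)/n)) / (1 - exp(2*ll0/n))`, clamped
to [0, 1]; `ll1 < ll0` beyond tolerance is an error since the larger model
contains the smaller.

## Matching statistics

The two-proportion z test pools the two samples for its variance estimate —
the convention that reproduces study-style statistics from raw counts — and
reports df = n1+n2−2 for display parity. A pooled proportion of exactly 0
or 1 degenerates to z = 0 with a flag. One-way ANOVA reports the
between/within mean-square ratio on (k−1, n−k) df; zero within-group
variance with unequal means reports an infinite F with a flag.

## Synthetic cohorts

The generator emulates the study conditions: 19 preserved-LH patients, 13
preserved-RH patients, 51 controls; two scanners with the study's per-group
assignment split (36/51 of controls and 13/32 of patients on the first);
ablation fractions 7/19 and 2/13 by group; ages uniform on 6–25 years
(an age-matched mode resamples patient ages with jitter for controls);
gender Bernoulli(½). Every non-gross value follows the additive model the
pipeline assumes — baseline + group effect + age slope + gender offset +
scanner shift + scanner-scaled Gaussian noise — with per-region baselines
spread deterministically over 0.6–1.4× the measure default. Defaults
(thickness 2.55 mm, SD 0.12; area 2400 mm², SD 230; cortical volume
5600 mm³, SD 540; subcortical 3400 mm³, SD 340; scanner shift 0.5 SD and
scale 1.2 on the second scanner; group effects zero) are field-realistic
choices fixed once; the residual distribution of real morphometrics is not
published, so Gaussian noise is a modelling choice. Gross volumes are
hierarchical: a hemisphere total (mean 470 cm³) split into GM/WM/LV by a
Dirichlet draw, so CV normalization has a well-defined denominator.

What the generator does **not** emulate: spatial correlation between
regions, non-Gaussian tails, lesion geometry, or segmentation failure
modes. Tests passing on generator output therefore demonstrate the
statistical machinery (effect recovery, calibration, determinism), not
robustness to those real-data features.

## Problem sizes used in validation

The validation suite uses reduced vocabularies (1–4 cortical regions) for
speed where region count is irrelevant to the property checked, and these
replication counts: 50 instances for exhaustive-oracle agreement at n=8;
500 null cohorts for type-I calibration; 20 replicate cohorts at
n=200/scanner for harmonization recovery; 1,000 random vectors for the BH
oracle; 200 cohorts (n=80, one 2-SD signal among 9 noise candidates) for
forward-selection recovery.

## Known limitations

* **Group-stratified winsorization is anti-conservative at small n.**
  Clipping each group at its own percentiles preserves the chance
  between-group offset while shrinking exchangeable noise; a permutation
  test run afterwards rejects too often. Measured: at n=19 vs 51 on pure
  N(0,1) data, per-group winsorization raises the 5% rejection rate to
  ≈0.07 (pooled winsorization stays at ≈0.04). Covariate-preserving
  harmonization with estimated per-scanner scale adds a similar
  small-sample effect (≈0.04 → ≈0.067 on null two-scanner cohorts). The
  full preprocess→permutation pipeline measures ≈0.10 on 500 null study-
  sized cohorts. The stratification is kept because it is the procedure
  this pipeline implements; analysts wanting exact calibration should pool
  strata or winsorize inside the permutation loop.
* The strict exceedance rule can return p = 0; use the smoothed rule when
  p-values feed calibration-sensitive downstream steps.
* In-sample Nagelkerke R² from forward selection is optimistic; no
  cross-validated performance is computed.
* BF01 magnitudes are tied to the BIC approximation.
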