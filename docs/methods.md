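# Methods

`melrad` re-implements, as a tested library, a pre-treatment FDG-PET
radiomics analysis that predicts 1-year progression-free status (1y-PFS) in
metastatic cutaneous melanoma treated with first-line immune checkpoint
inhibitors, and stratifies progression-free and overall survival by the
resulting classifier. The original patient registry is not redistributable,
so the package ships a synthetic-data module that reproduces the *structure*
of the two-center study; everything downstream is exercised and tested
against that structure.

## Imaging model and segmentation

SUV volumes are trilinearly resampled to isotropic 1 mm voxels (masks by
nearest neighbor). The new grid shares the input origin and places voxel
centers every millimeter inside the old grid's extent, so resampling a
volume already at 1 mm is an exact identity.

Tumor burden is segmented by a liver-referenced threshold in the PERCIST
tradition: a 3-cm spherical VOI yields the liver mean μ and population SD σ
(sphere membership is voxel-center-within-radius, inclusive at exactly the
radius; the population rather than sample SD is a documented choice, the
convention being otherwise unspecified), and the threshold is

    T = 1.5 μ + 2 σ.

Voxels with SUV ≥ T (inclusive), minus user-supplied exclusion masks
standing in for manual corrections of physiological uptake (brain, kidneys,
bladder), are grouped by 26-connectivity; components under 64 voxels
(64 mm³ at 1 mm spacing, configurable) are dropped to suppress noise
specks. All surviving components are merged into one tumor mask for feature
extraction; per-lesion extraction with aggregation would be a defensible
alternative, but a merged mask is the simpler reading of a whole-body
tumor-burden analysis and is what the pipeline implements.

## Radiomic features

Each patient contributes 856 features: 93 intensity/texture features
(18 first-order, 24 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM) on each of
9 image types — the original SUV volume and the 8 sub-bands (LLL…HHH) of a
single-level *stationary* (undecimated) separable coif1 wavelet transform —
plus 14 shape features and 5 supplementary first-order features
(StandardDeviation, CoefficientOfVariation, the 25th/75th percentiles and
total lesion glycolysis) on the original image only:
93 × 9 + 14 + 5 = 856. Only the total is externally fixed; the composition
is the package's documented registry and is serialized as a plain-text
identifier list.

Numerical choices:

* The stationary transform is shape-preserving, so one mask indexes every
  sub-band. Filtering is periodic (PyWavelets `swtn`); odd axes are
  edge-padded to even length and cropped back. Sub-band letters follow axis
  order (first letter = filter along axis 0). The volume is cropped to the
  mask bounding box with a 12-voxel margin (beyond the coif1 support)
  before the transform, purely for speed.
* Gray levels use a fixed bin width of 0.1 (SUV units on the original
  image, sub-band units on wavelet images), anchored at each image's
  in-mask minimum: level(x) = floor(x/w) − floor(min/w) + 1. Anchoring at
  zero would be ill-defined for signed sub-band intensities.
* Directional matrices (GLCM, GLRLM) use the 13 unique distance-1
  directions; feature values are computed per direction and averaged.
  GLCM counts are symmetric. GLDM uses α = 0 (neighbors are dependent only
  at the identical level) over the 26-neighborhood; dependence *size*
  counts the center voxel. NGTDM excludes voxels with no in-mask neighbor.
* Degenerate regions (single voxel, constant intensity) produce the
  documented fallback 0 with a warning rather than NaNs; on a constant
  region every variance/prominence-type feature is exactly 0.
* Shape features come from a marching-cubes mesh of the 0.5-isosurface
  (volume by the divergence theorem) and from principal axes of the
  physical voxel coordinates (4·sqrt(eigenvalue) convention).

Every texture family is verified against naive loop-based oracle
implementations (tests/oracles.py) to 1e-9 on random 4×4×4 regions.

## Harmonization

Center/batch effects on the feature tables are removed by reference-batch
ComBat: features are standardized by the reference batch's mean and SD,
non-reference batch location (γ) and scale (δ²) estimates are shrunk by
parametric empirical Bayes (normal prior on γ, inverse-gamma on δ², method
of moments hyperparameters, iterated conditional means to 1e-6, at most 100
iterations), and adjusted values are mapped back to the reference scale.
The reference batch is an exact fixed point — this is what guarantees that
the testing cohort can contribute batch statistics without influencing any
development-cohort value. Features constant in the reference batch cannot
be standardized; they are flagged, excluded from the shrinkage pool, and
passed through unchanged. No biological covariates enter the design: the
harmonization target is scanner/center variation only.

Two properties deserve a note. First, EB shrinkage deliberately leaves each
feature's residual batch difference at a fraction of its sampling noise
(that is the bias/variance trade the prior buys), so shift removal is
checked in aggregate (mean and median residual across features) rather
than per feature. Second, a frozen affine adjustment is not a projection:
applying the fitted transform twice is *not* the identity, and with EB even
refitting on the model's own output only approaches neutrality. The exact
refit-idempotence contract holds for the `shrink=False` location/scale
variant, which maps each batch's moments exactly onto the reference scale;
both behaviors are tested. The implementation is cross-checked against
Bioconductor's `sva::ComBat` with `ref.batch` on a small fixture.

Whether harmonization should be fit on both cohorts jointly or frozen
before seeing the testing cohort is ambiguous in the underlying design;
because the reference batch is a fixed point, the development data are
identical either way, and the pipeline fits on the combined table while
persisting the model for later out-of-sample application.

## Feature selection

Step 1 keeps features associated with 1y-PFS status by a two-sided
Mann-Whitney test at p < 0.05 — exact enumeration for tie-free groups of at
most 20, normal approximation with tie correction otherwise; constant
features get p = 1. No multiplicity adjustment is applied at this
exploratory stage (redundancy is handled next, and the external cohort
guards against overfitting). Step 2 walks the retained set in ascending-p
order (ties broken lexicographically) and keeps a feature only if its
absolute Spearman correlation with every already-kept feature is ≤ 0.7;
"keep the most significant member of each correlated group" is ambiguous in
general, and this greedy keep-first-by-p reading is deterministic,
certificate-checkable (all pairwise |ρ| ≤ 0.7 afterwards) and logged pair
by pair. Selection sees only the development cohort.

## Classifier and operating point

The classifier is a single-hidden-layer perceptron (default 4 hidden
units — the width is not externally specified; a small width suits
cohorts of ~60 training patients and 3-feature models). Features are
standardized to training mean/SD. The model family was originally
specified with a scaled-conjugate-gradient optimizer (initial λ = 5e-7,
σ = 5e-5, uniform init on ±0.5); this implementation trains with seeded
L-BFGS restarts (best of `n_restarts` by final loss), which is
deterministic, robust on tiny datasets, and passes the same separability
contracts (XOR with 4 hidden units; AUC > 0.95 on well-separated
Gaussians). The SCG fields are retained on `MlpHyperparams` as a record.

The development cohort is split 60/40 (stratified) into training and
validation. Within the training split, stratified 10-fold cross-validation
produces out-of-fold probabilities and per-feature importance; "importance"
is realized as permutation importance (mean out-of-fold log-loss increase
over 20 shuffles), converted to ranks (ties lexicographic) and averaged
over folds. Backward elimination repeatedly drops the worst-ranked feature;
at each set size a model trained on the full training split is scored on
the validation split, scanning probability thresholds in 0.5% steps and
maximizing

    EFF = P·Se + (1 − P)·Sp,   P = observed event prevalence,

with ties resolved toward the smallest threshold. The feature set and
threshold with the highest validation EFF (ties → fewer features) define
the final model. A patient is called positive when the predicted
probability strictly exceeds the threshold. The frozen model and threshold
are then applied unchanged to the external testing cohort; performance is
reported as the confusion counts, Se, Sp, PPV, NPV, prevalence, EFF,
rank-based AUC (Mann-Whitney identity) and the thresholded C-statistic
(Se + Sp)/2, with zero-denominator ratios flagged as undefined rather than
zeroed.

An alternative reading — cross-validating over the whole development cohort
rather than its training split — exists; the implementation keeps CV inside
the training split so the validation split touches nothing but EFF-based
selection.

## Survival analysis

PFS is time to progression or death, OS time to death; non-events are
censored at last follow-up; months are the time unit; 1y-PFS status is an
event at ≤ 12.0 months (inclusive). Kaplan-Meier estimation, the two-group
log-rank test (1 df) and Cox proportional-hazards models (Efron ties, Wald
95% CIs — the usual clinical reporting convention) are delegated to
lifelines behind small result types; Greenwood variances are recomputed
from the event table. Monotone-likelihood fits (perfect separation in
time) are detected by divergent coefficients and refit with a small ridge
penalizer, with a warning recorded on the result. The multivariable screen
enters every covariate with univariable p < 0.20. Cox estimates are
verified against a brute-force partial-likelihood oracle on tie-free
fixtures and by recovery of a simulated hazard ratio of 2.7 (within 15%
averaged over 50 replicates at n = 95, ~60% events) — the magnitude the
stratified analysis is expected to detect.

## Synthetic data: what it emulates, and what it does not

`PhantomSpec` renders SUV volumes with a liver sphere (Gaussian intensities
around a configurable mean/SD), spherical lesions whose amplitude must
exceed the implied threshold (smooth or "speckled" — a unit-mean lognormal
multiplier that gives lesions non-degenerate texture), optional hot organ
spheres meant to be excluded, and additive Gaussian noise, clipped at 0.
Default grid 48×32×32 at 2 mm (resampled to 1 mm downstream), liver mean
2.0/SD 0.25, one 8-mm speckled lesion at SUV 8, noise SD 0.1 — values in
the range routinely quoted for FDG-PET liver background and melanoma
lesions.

`CohortSpec` draws a development cohort (n = 95, 1-year event probability
0.484) and a testing cohort (n = 59, probability 0.407) — the sizes and
event rates of the study the analysis is modeled on. Features are standard
normal; three planted features are shifted by 1.0 SD in 1-year progressors
(a moderate, detectable radiomic effect); each center then applies
x → δ·x + γ (defaults γ = 0.5, δ = 1.25 on center 2 — the study does not
report per-center feature distributions, so batch magnitudes are free
parameters chosen to be large enough that un-harmonized analyses visibly
degrade). When the feature count is 856 the columns carry the registry
identifiers, so the planted features are real feature names.

Survival times follow a proportional-hazards construction on the latent
1-year risk: progressors fail within 12 months at hazard
λ₀·exp(β) (λ₀ = 0.057/month, β = 1.0 ≈ log 2.7, via the inverse CDF of the
truncated exponential, median ≈ 4.5 months); non-progressors survive the
first 12 months and continue memorylessly at λ₀, censored administratively
at 60 months with 20% uniform dropout after month 12 (dropout before month
12 is excluded so the 1-year status is always determined). OS adds an
exponential post-progression increment (rate 0.116/month, median ≈ 6
months), so OS ≥ PFS by construction. Binary clinical covariates are drawn
at the prevalences typical of such cohorts and are independent of outcome —
matching the finding that no clinicobiological factor reached significance.

What the generator does *not* emulate: realistic anatomy, scanner physics
(attenuation, scatter, reconstruction), correlated feature blocks (real
radiomic features are heavily redundant — which is why the real analysis
collapsed 46 features to 3 at the Spearman step, while synthetic
independent features mostly survive it), non-proportional hazards, or
informative censoring. Green tests therefore certify the estimators and
the workflow logic, not clinical performance on real images; the published
cohort-dependent numbers (AUC 0.74, the 55% threshold, the hazard ratios)
are not reproduction targets.

## Problem sizes and runtime choices

The default end-to-end pipeline simulates both cohorts at full size
(95 + 59 patients × 856 features), runs the imaging demo on the default
phantom, and caps the backward-elimination start at the 25 most significant
selected features — with independent synthetic features the Spearman step
prunes little, and eliminating from ~45 features would roughly quadruple
runtime for no additional coverage. A full run takes on the order of two
minutes on one CPU and is bit-reproducible under a fixed seed. Property
tests that average over seeds use 10–50 replicates, chosen so that their
binomial/Monte-Carlo error is well inside the asserted bands.

## Known limitations

* The registry composition behind the 856 total is a reconstruction; only
  the total is externally checkable.
* Texture aggregation (direction-averaging, merged tumor mask) follows
  common radiomics practice where the source analysis is silent.
* The lbfgs-based perceptron is a substitute for the original SCG
  implementation; probabilities will differ from SPSS Modeler's even on
  identical data, though the workflow contracts are preserved.
* EB-ComBat shift removal is aggregate, not per-feature (see above).
* The printed development efficiency of 50.5% is not reproducible from the
  printed Se/Sp/prevalence under the stated EFF formula; it is treated as
  an internal inconsistency of the source report and not asserted anywhere.
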