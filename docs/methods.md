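# Methods

## The compensation model

`compmap` operationalizes neural compensation in premanifest Huntington's
disease (preHD) as a moderated regression. For a performance measure *y*, a
structural disease-load measure *d*, an fMRI signal *f* and covariates **c**,

    y = α + β₁·d + β₂·f + β₃·d·f + γ·c + e,      e ~ N(0, σₑ²),

where α is the intercept, β₁ and β₂ are main effects, β₃ is the interaction
between disease load and fMRI signal, γ is the covariate coefficient vector
and e is Gaussian error. Evidence for compensation is rejection of
H₀: β₃ = 0 — the performance–activity relationship varies with disease load.
Disease load is a regional volume (caudate, putamen, global gray, global
white) expressed as a fraction of total intracranial volume and analyzed one
at a time, so **small d means high load**. Covariates are age, gender, study
site, education level and the cumulative probability of onset (CPO).

Model conventions:

- Ordinary least squares on `[1, d, f, d·f, c]`; heteroscedasticity is not
  modeled. The test of β₃ is two-sided by default (effects are reported in
  both directions); one-sided alternatives are available.
- Significance uses the nominal p ≤ 0.05 criterion with **no** adjustment
  across features or voxels. The only pre-planned multiplicity correction is
  Bonferroni across the four disease-load measures (α/4 = 0.0125).
- Gender enters as a 0/1 indicator, site as reference-coded indicators
  against the first site, education as an integer level (ISCED-style), CPO
  as a probability. Complete cases only: rows missing any model variable are
  dropped, never imputed.
- d stays on its raw fraction scale. The interaction t and p are invariant
  to centering d and to affine rescaling of f (verified by property tests),
  so this choice affects only the interpretability of β₁/β₂, not inference.
- Collinearity guard: the fit refuses designs whose (column-normalized)
  condition number exceeds 1e8 and names the offending columns.

### Pattern classification

A significant β₃ is classified from the fitted performance–activity slope
s(d) = β₂ + β₃·d evaluated at the extremes of the observed load range
(defaults: 10th and 90th percentiles of d). The pattern is *compensatory*
when the slope at high load (small volume) exceeds the slope at low load and
is positive — coupling that strengthens with atrophy while remaining
performance-supporting; otherwise it is *non-compensatory* (slope weakens
with load, or is negative at high load). Slopes over the observed range are
used rather than the sign of β₃ alone because the coefficient's sign by
itself says nothing about where the slope sits relative to zero. Under joint
negation of (f, β₂, β₃) the labels swap — the positive-relationship
requirement is part of the definition, so the orientation of f is
meaningful, not arbitrary.

### Voxelwise application

For task fMRI the model is fitted independently at every voxel inside the
task main-effect mask (group one-sample t on the contrast maps, Bonferroni
FWE α = 0.05), with f the voxel's contrast value; findings are reported at
p < 0.001 uncorrected. The per-voxel solver uses a QR decomposition per
voxel and is bit-for-bit consistent with the single-feature fit (a one-voxel
mask reduces exactly to `fit_compensation`); tests verify equality with an
independent pseudoinverse route to 1e-8 and with statsmodels.

## Imaging operations

- **Smoothing**: separable Gaussian kernel, σ = FWHM/(2√(2 ln 2)) per axis in
  mm converted to voxels through the affine column norms (default FWHM 6 mm).
  Sheared/oblique affines are rejected rather than silently mishandled. 4D
  images are smoothed frame-wise in space only.
- **Sphere extraction**: a region is the set of voxels whose centres lie
  within the radius (default 4 mm) of the mm coordinate — voxel-centre
  membership, no partial volumes — and the feature is the mean series.
- **First-level GLM**: block boxcars convolved with a canonical double-gamma
  haemodynamic response (gamma densities peaking at 6 s and 16 s, undershoot
  ratio 1/6 — the common SPM-style convention), sampled at the TR, plus six
  motion regressors, labelled nuisance columns and an intercept; per-voxel
  OLS; a contrast image is a weighted coefficient combination (e.g. 2-back
  vs 1-back). The first four frames are discarded before fitting (dummy
  scans before steady state). Temporal autocorrelation is ignored (OLS, not
  prewhitened GLS): group-level inference on the resulting contrast maps
  does not rely on first-level error variances, and the synthetic series
  carry no autocorrelation by construction.
- **Seed connectivity**: seed and voxel series are residualized against
  white-matter, CSF and six motion regressors (plus intercept); the map
  value is the Fisher z of the partial correlation. z is capped at
  atanh(1 − 1e-7) ≈ 8.38 (self-correlation would be infinite); voxels whose
  variance the nuisance fully explains map to 0. Partial correlation was
  chosen over raw correlation of residual maps because it has a clean
  sampling theory and reduces exactly to the plain correlation when no
  nuisance is supplied.
- **Group inference**: voxelwise one-tailed (positive) one-sample t across
  subjects' z maps, df = n − 1. Family-wise error control is Bonferroni over
  in-mask voxels by default (deterministic, conservative), with sign-flip
  maximum-statistic permutation as an option; random-field-theory FWE is
  deliberately out of scope. Surviving voxels are grouped by 26-connectivity
  with minimum cluster size 1. Seed-sphere voxels are not excluded from maps
  or clusters; the seed cluster is reported so users can mask it.

## Synthetic cohort generator

The generator emulates the study conditions every analysis stage is
validated against: ~100 gene-carriers and ~100 controls across 4 sites
(defaults 106/111), TR 3 s, 165 resting volumes, with a desk-scale 24×28×24
grid at 4 mm.

- **Recruitment**: carriers have CAG ≥ 40 drawn uniformly on 40–47 and a
  disease-burden score age·(CAG − 35.5) > 250 enforced by resampling, ages
  ~N(43, 9²) clipped to 23–64; controls ~N(48, 10²) with normal-range CAG.
- **CPO surrogate**: the onset-probability covariate is a logistic function
  of disease burden, expit((burden − 350)/80), giving carriers a 0.2–0.97
  spread; controls are 0. This is a monotone-in-burden surrogate — the shape
  and constants are this package's choice, not an estimate of any published
  onset model.
- **Atrophy**: volume fractions decline linearly in CPO with Gaussian noise
  (gray 0.50 − 0.08·CPO ± 0.015; white 0.33 − 0.03·CPO ± 0.012; caudate
  0.0048 − 0.0015·CPO ± 0.0004; putamen 0.0065 − 0.0020·CPO ± 0.0005),
  clipped to (0, 1). The linear-in-CPO structure is the simplest that gives
  the d-variance the interaction model needs; means and spreads are typical
  volumetric magnitudes for these structures.
- **Planted interaction**: the latent task feature f ~ N(0, 1) is drawn
  first and the continuous working-memory performance score is generated
  from the model above with defaults α = −0.55, β₁ = 4, β₂ = 6, β₃ = −12 on
  the gray-matter fraction, σₑ = 0.5. Over the carriers' observed gray
  range (~0.40–0.50) the slope β₂ + β₃·d runs from ≈ +1.2 at high load to
  ≈ 0 at low load: a compensatory pattern of roughly half a performance SD.
  Drawing f first (rather than solving f from an independently generated y
  with a second noise draw) keeps the regressor exogenous; both
  constructions satisfy the model identity, but only this one leaves OLS
  unbiased, which the calibration and coverage studies require. Because the
  model is generated on the gray fraction and the other three loads co-vary
  with it through CPO, analyses against caudate/putamen/white recover
  attenuated interactions — mirroring the pattern of partially concordant
  loads real studies report.
- **Task images**: per-subject 3D contrast maps are spatially smooth
  background noise (white noise filtered at 6 mm FWHM, rescaled to SD 0.8)
  plus fixed Gaussian main-effect blobs (amplitude 3, σ 4 mm) at the effect
  coordinates; at the single designated compensation voxel the value is
  amplitude + f. The additive offset is harmless: the interaction test is
  invariant to affine rescaling of f.
- **Resting series**: a latent time course drives a seed region (4 mm
  sphere, voxel noise SD 0.2); a target region (6 mm sphere, voxel noise SD
  0.1) follows it with per-subject coupling ~N(0.6, 0.15²) clipped to
  (0.05, 0.95). Global white-matter and CSF confound series (weights 0.8 and
  0.5) and a mild leakage of the first motion trace (0.15 of its
  standardized random walk) are added to every voxel and reported, with all
  six motion regressors, in the subject's nuisance table. The latent
  cognition score follows the same compensation model with f = atanh of the
  coupling, and the nine-test battery loads on that latent factor
  (loadings 0.60–0.85), so the PCA composite inherits the planted structure.
- **Behavioral columns**: n-back hit/false-alarm counts are binomial
  realizations whose success probabilities track the continuous performance
  score; they exist so the d-prime operation has realistic inputs. The
  compensation outcome is the continuous score itself — forcing y to equal
  the quantized, bounded count-based score would break the Gaussian-error
  model the calibration studies assume. Motor outcomes (a clinician-style
  motor score rising with CPO, grip-force variability) carry **no** planted
  interaction, so the motor branch is a built-in negative control.
- **Determinism**: all randomness flows from one seed through independent
  named streams (table / task images / per-subject rest series), so any
  stage can be regenerated in isolation and identical seeds give
  byte-identical outputs.

### What the generator does not emulate

No hemodynamic nonlinearity, no physiological noise spectra, no temporal
autocorrelation in the resting series, no scanner-site intensity effects
beyond an additive site mean shift on performance, no motion artifacts
beyond a global linear leakage, and atrophy that is linear in CPO. Passing
tests therefore demonstrate statistical correctness of the estimators and
decisions under the stated model — not robustness to the full noise
structure of real EPI data.

## Behavioral measures

- **n-back score**: hit probability minus false-alarm probability, bounded
  in [−1, 1]. This is deliberately the simple probability-difference form,
  not the classical z-transformed d′.
- **Global cognitive composite**: columns are orientation-corrected (flagged
  lower-is-better tests negated), standardized to mean 0 / SD 1 over the
  analysis sample (carriers and controls pooled — whether to standardize
  against controls only is genuinely open; pooling was chosen as the less
  assumption-laden default), and the composite is the subjects' scores on
  the first principal component, sign-oriented so the mean loading is
  positive (higher = better). Missing values raise; constant columns raise.
  The module is test-agnostic: any nine labelled columns qualify.

## Conditioning plots

Interval construction follows the classic equal-count algorithm: for n
observations, k intervals and overlap fraction r, the target count is
m = n/(k(1−r)+r) and interval j spans sorted ranks round((j−1)·m·(1−r))
through start+⌈m⌉−1, clipped to the data. Each interval then gets an
illustrative least-squares line of y on f — display only, never inference.
With k = 4, r = 0.5, n = 100 this yields counts of 40 ± 1 sharing 20 ± 2
points between neighbours (verified by brute force).

## Validation studies and problem sizes

`compmap.validation` (driven by `scripts/acceptance.py` and the acceptance
tests) recomputes:

- **Type-I calibration**: 1000 null cohorts (β₃ = 0, 100 carriers); the
  nominal p ≤ 0.05 test should reject at 5% within Monte-Carlo error.
- **Recovery**: 200 cohorts with the planted β₃; 95% CI coverage and mean
  bias of the estimate.
- **Oracle equivalence**: voxelwise maps vs independent per-voxel
  pseudoinverse regression over a full 24×28×24 volume (16 128 voxels),
  agreement to 1e-8.
- **End-to-end detection**: 20 seeded full-pipeline runs on a demo cohort of
  100 carriers + 60 controls with 80 resting volumes; the planted
  compensation voxel should be the minimum-p in-mask voxel, and the planted
  resting-state target inside an FWE-significant cluster, in ≥ 90% of runs.
  The carrier count matches the reference design because the interaction
  test's power lives there; controls (who only enter the group-mean maps)
  and the series length are scaled down to keep a full cycle ~10 s.
- **Coplot counts** and the **worked behavioral examples** (exact values).

## Numerical choices

- OLS via thin QR (`solve_triangular` back-substitution); standard errors
  from the inverted triangular factor. Zero-variance voxels in group t maps
  get a capped t of ±1e6 with the corresponding limiting p.
- Fisher z uses r clipped to ±(1 − 1e-7).
- Coplot rank arithmetic uses round-half-up for determinism across
  platforms; ties in d are broken by stable sort order.
- Images are written as float32 NIfTI-1 with RAS affines; all internal
  computation is float64.

## Known limitations

Single-timepoint (cross-sectional) modeling only; the four disease loads are
tested one at a time, never integrated multivariately; no effective
connectivity; no bandpass filtering or scrubbing of resting series; Bonferroni
FWE is conservative relative to random-field or permutation methods on smooth
maps (permutation is available where that matters). The synthetic-data caveats
above bound what green tests imply about real cohorts.
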