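# Methods

This note documents the models implemented in `cortexmeta`, the numerical
choices behind them, what the synthetic data do and do not emulate, and the
study conditions used by the test suite and `scripts/acceptance.py`.

## Surface geometry and smoothing

The analysis domain is a triangulated surface with a matched unit-sphere
registration and a boolean cortex mask.  Synthetic meshes are icospheres
(`10·4^L + 2` vertices at subdivision level L) built with a deterministic
midpoint-cache subdivision so that seeded simulations are bit-reproducible;
the default radius of 100 mm approximates a registered cortical template
sphere.  Per-vertex surface area assigns each vertex one third of its
incident triangle areas, so vertex areas tile the sheet exactly.

Smoothing is iterated graph diffusion.  The one-step operator keeps weight
0.5 on the vertex and spreads 0.5 over valid first-ring neighbours using
Metropolis weights (`1/max(deg_i, deg_j)` per edge, remainder returned to
the diagonal).  Uniform first-ring weights were rejected because they are
asymmetric wherever vertex degree varies (every icosphere has twelve
degree-5 vertices), and an asymmetric row-stochastic operator does not
preserve the mean; the Metropolis construction is symmetric and doubly
stochastic, so constants are fixed points, the masked mean is preserved to
machine precision and the variance is non-increasing.  Masked (medial-wall
analogue) vertices are excluded from the weights entirely rather than
zero-filled, which avoids attenuation at mask borders.

The iteration count is calibrated so a point source spreads to a requested
geodesic FWHM: one iteration adds per-axis variance
`v1 = mean_i Σ_j W_ij |x_j − x_i|² / 2` (the factor 2 converts the 2-D
squared displacement to a per-axis variance), and
`n = round(sigma²/v1)` with `sigma = FWHM/√(8 ln 2)`.  An empirical
point-source test on an L=5, radius-100 sphere measures the realized FWHM
at 18.9–20.9 mm for a requested 20 mm at generic (hexagonal) vertices; the
twelve pentagonal vertices have anomalously short edges and measure a few
mm narrower, so calibration tests use a generic source vertex.

## Synthetic cohorts

`simulate_cohort` generates what a qcache-style pipeline hands to a group
analysis: *already smoothed* subject × vertex morphometry.  The latent
factor is `g_i ~ N(0,1)`; test scores follow the one-factor model with
default loadings (0.8, 0.7, 0.6, 0.5, 0.4), uniquenesses `1 − λ²`, and
completely-at-random missingness (default 10%, enough to exercise the
casewise-likelihood path; informative missingness is out of scope).
Morphometry is built directly on the standardized (correlation) scale:

```
y_iv = (beta_v + delta_v)·g_i + beta_age,v·age_z + beta_sex,v·sex_z
       + beta_site·site_z + sqrt(1 − R²_v)·e_iv
```

with `delta_v ~ N(0, tau²)` a smooth cohort-level deviation field and
`e_iv` a unit-variance random field smoothed to `noise_fwhm_mm`
(default 20 mm).  Because everything is standardized, the configured effect
maps *are* the expected sample standardized betas — raw-unit data are a
per-vertex affine rescaling away and the standardized GLM is invariant to
it.

Default effect magnitudes are chosen to reflect adult morphometry studies,
where age and sex effects dwarf cognition effects: g-effect maps have
spatial mean 0.05 and SD 0.05 (the published vertex-wise g–morphometry
range is roughly −0.12 to 0.17), age-effect maps mean −0.35 and SD 0.2,
sex-effect maps mean 0.3 and SD 0.15, site 0.15, all clipped to
correlation-scale bounds (0.3 / 0.65 / 0.5) so per-vertex explained
variance stays below 1.  Age and sex maps are orthogonalized against the
g map (Gram–Schmidt over the cortex mask) so covariate-adjustment tests
have an exact known answer.  Effect maps use 10 mm smoothness — finer than
the 20 mm residual fields, since biological effect patterns are not bound
to the analysis smoothing kernel.  Between-cohort heterogeneity defaults
to `tau = 0.03`; no quantitative value is published for this, so it is a
free simulation parameter chosen to be of the same order as the
within-cohort standard error at n ≈ 1000.

What the generator does *not* emulate: realistic folding geometry,
scanner- or FreeSurfer-version-specific artefacts, informative
missingness, and non-Gaussian residuals.  Passing tests therefore
demonstrate the correctness and calibration of the estimators under the
stated generative model, not robustness to those real-data features.

## One-factor model

Estimation maximizes the casewise Gaussian likelihood over
`(mu, lambda, log psi)` (L-BFGS-B with analytic gradients, gradient
tolerance 1e-8, at most 500 iterations, `psi` floored at 1e-6 with
Heywood flagging).  With missing data this is full-information ML,
grouping subjects by missingness pattern; `complete_case` first applies
listwise deletion and then maximizes the same casewise likelihood, so the
two estimators coincide exactly on complete data.  Identification is by
unit factor variance (symmetric treatment of tests) with the mean loading
oriented positive.  The chi-square is `2(ll_saturated − ll_model)`, the
saturated model fitted by EM under missingness; the independence baseline
fits per-variable normals.  CFI, TLI and RMSEA use the standard formulas
(RMSEA with an `n − 1` denominator); SRMR is the RMS standardized residual
against the saturated covariance over unique elements including the
diagonal.  Factor scores use the regression (Thomson) method on each
subject's observed submatrix; subjects with no observed tests get NaN.
Scores are reported oriented to correlate positively with the mean
standardized test score (higher = better performance).

## Vertex-wise GLM

Ordinary least squares per vertex with design
`[intercept, focal, covariates]`, categoricals dummy-coded against a
first-level reference.  The focal coefficient and its SE are standardized
by `SD(focal)/SD(y_v)` computed on the analysis sample after listwise
deletion — standardizing the SE by the same factor keeps t and p invariant
to affine rescaling of either variable.  Zero-variance vertices are
flagged invalid; rank-deficient designs raise an error naming the
offending column.  With no covariates the standardized slope equals the
Pearson correlation to machine precision, which is the module's primary
contract.

## Random-effects meta-analysis

Per vertex, inverse-variance pooling with weights `1/(se² + tau²)`.
`tau²` estimators: DerSimonian–Laird closed form, or REML (default, the
convention of standard meta-analysis tooling).  The REML estimate solves
the restricted-likelihood score equation by safeguarded bisection
(truncated at zero, bracket expanded adaptively, tolerance 1e-12); the
earlier fixed-point iteration was replaced because it can stall within
~1e-4 of the optimum at k = 3.  Inference is Wald z by default (matching
common tooling), with Knapp–Hartung available.  Vertices with invalid
cohorts are pooled on the available k ≥ 2, else flagged invalid.  FDR is
Benjamini–Hochberg over the valid cortex vertices of one map.  The
moderator meta-regression is weighted least squares with `tau²`
re-estimated by the method of moments on the weighted residual
heterogeneity (hat-matrix trace correction) — a REML meta-regression was
judged out of proportion for the single-moderator use case.

With equal within-cohort SEs, DL and REML truncate to zero under exactly
the same condition (Q ≤ k−1); with unequal SEs the truncation boundaries
differ slightly, so the agreement property is asserted for equal SEs.

## Spin test and regional decomposition

Uniform random rotations are sampled as normalized 4-D Gaussian
quaternions from a counter-based (Philox) stream, so ensembles are
reproducible and shardable; for bilateral meshes the right hemisphere
receives the x-mirrored rotation and assignments stay within hemisphere.
Each target vertex takes the value of the nearest rotated source vertex
(great-circle nearest neighbour); a spun value is used only if its source
vertex is valid, with pairwise deletion per spin.  The p-value is
two-sided on |r| with the add-one formula, so the smallest attainable p
with S spins is `1/(S+1)`.  Type-I calibration on independent 20 mm fields
(L=4 mesh, 200 spins) lands near the nominal 5% level, and may run
slightly conservative at coarse resolutions.

Within-region correlations are plain Pearson r over each region's jointly
valid vertices; regions under `min_vertices` (default 25) are reported
missing rather than dropped.  The exact ML-covariance identity
`Cov_total = Σ_g (N_g/N)·Cov_within_g + Cov_between(weighted means)`
is asserted to 1e-10 and explains how opposite-signed regional
correlations can cancel at cortex level (Simpson-type structure).

## Map decomposition

Stacking intersects validity masks and z-scores each map over the joint
mask (ddof 1), making the PCA a correlation-matrix eigendecomposition.
Loadings are `eigvec·√eigval`; components are oriented so the
largest-|loading| map loads positively (deterministic across platforms).
Varimax is the SVD-based Kaiser iteration (row-normalized by default,
criterion tolerance 1e-10); rotated variance shares are sums of squared
rotated loadings over the total, rotated components are re-ordered by
variance, and communalities are preserved to 1e-9 by orthogonality.
Rotated scores are computed by regression of the z-scored stack on the
rotated loadings, which for PCA loadings equals rotating the principal
scores and therefore stays exactly orthogonal.  Tucker's congruence
`φ = Σab/√(Σa²·Σb²)` is the uncentred cosine, deliberately not Pearson r.

## Allometric scaling

Per vertex, OLS of `ln(vertex area)` on `ln(total area)` (natural log;
the slope is base-invariant).  Slopes are returned raw (1 = isometry) and
standardized with the same SD-ratio convention as the g models; covariates
are optional and default to none.  Vertices with any non-positive area are
invalidated with a logged count.  Cohort maps are pooled with the same
random-effects machinery as the g analyses.

One property worth recording: the *standardized* allometric slope divides
by SD(ln vertex area), which itself grows with the local exponent, so when
vertex-level log noise `s` is small the exponent signal cancels out of the
standardized map.  For brain-scale log SD `t`, exponent-map spatial SD
`s_k` and n subjects, the expected cross-cohort correlation of
standardized slope maps is `1/√(1+((t²+s²)/(√n·t·s_k·s))²)`, maximized at
`s = t`.  The cross-cohort consistency test therefore uses exponent-map
SD 0.2 (published allometry maps span roughly 0.5–1.5) with ~10%
vertex-level log noise at n = 500 per cohort.

## Study conditions for the acceptance checks

All sizes were chosen once, as the smallest configurations that make the
statistical properties sharp:

- Meta-analysis oracles: the two-cohort closed-form example and 1000
  random k=3 problems against independent references (statsmodels DL /
  direct restricted-likelihood maximization for REML), tolerance 1e-6.
- Parameter recovery: 3 cohorts × 1000 subjects on an L=4 icosphere,
  g-effect map SD 0.05, tau 0.03, full covariate set; expected recovery
  correlation `1/√(1+(tau²+SE²)/(3·SD_beta²)) ≈ 0.91` — note that with no
  covariate signal (SE = 1/√n) this expectation falls below 0.9, so the
  realistic covariate magnitudes above are a necessary part of the design.
- Spin calibration: 500 independent 20 mm map pairs, 200 spins each,
  rejection rate at alpha = 0.05 expected in [0.02, 0.08].
- Factor model: λ = (0.8, 0.7, 0.6, 0.5, 0.4) at n = 5000 for recovery;
  100 replicates for the RMSEA distribution; exact-covariance construction
  for the perfect-fit boundary.
- Smoothing: 20 mm point source on the L=5, radius-100 sphere, measured
  FWHM within 15%.
- Decomposition: 33 maps from 4 latents (block loadings 0.8, noise SD
  0.2), rotated-loading congruence per column above 0.95.
- Allometry: exact isometry (slope 1 to 1e-8) and a 1.2-exponent region
  recovered within 0.05 at n = 500.
- Determinism: the full CLI chain (L=3 mesh, 3 cohorts of 300) rerun with
  identical seeds must reproduce byte-identical numeric outputs.

## Known limitations

- The spin test does not address heterogeneous spatial autocorrelation
  across the surface, and no variogram-matching null generator is
  provided.
- The one-factor model has no hierarchical/bifactor variants, residual
  covariances or measurement-invariance testing.
- The smoothing kernel is FWHM-calibrated, not kernel-equivalent to any
  specific surface-smoothing implementation.
- Synthetic meshes are spheres; FWHM is interpreted on the native
  geometry, which for spheres coincides with the registration sphere.
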