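# cortexmeta

Meta-analytic vertex-wise brain mapping: from cognitive test batteries and
surface morphometry to pooled cortical effect maps, their spatial
correlates, and the low-dimensional structure of cortical organisation.

## Who this is for

Imaging-genetics and brain-behaviour researchers who relate individual
differences (general cognitive function *g*, age, sex) to cortical
morphometry (volume, surface area, thickness, curvature, sulcal depth) at
the level of the registered surface vertex, pool those associations across
cohorts, and ask what neurobiological gradients the resulting maps
resemble.  Real cohort data of this kind are access-controlled, so the
package ships a first-class synthetic-data module that generates
multi-cohort subject × vertex datasets with known ground truth on
icosphere stand-ins for a registered cortical template — every stage of
the pipeline is testable end to end at the desk.

## The model

1. **Latent g** — a one-factor measurement model over a battery of
   cognitive tests, `x_ij = mu_j + lambda_j g_i + e_ij`,
   `Var(e_ij) = psi_j`, factor variance fixed to 1, estimated by casewise
   (full-information) maximum likelihood so missing test scores are used,
   with CFI / TLI / RMSEA / SRMR fit indices and Thomson regression factor
   scores oriented so higher = better performance.
2. **Vertex-wise GLM** — at each cortical vertex an OLS of morphometry on
   the focal predictor plus covariates (age, sex, site, head position);
   the focal slope is standardized, `beta = b · SD(x)/SD(y_v)`, a
   correlation-scale effect size.
3. **Random-effects meta-analysis** — per vertex, cohort betas are pooled
   with inverse-variance weights `1/(se² + tau²)`; tau² by REML (default)
   or the DerSimonian–Laird closed form, Wald z inference, optional
   Knapp–Hartung adjustment, cohort-level moderator meta-regression, and
   Benjamini–Hochberg FDR across the vertices of each map.
4. **Spatial inference** — Pearson correlations between maps with
   spin-based spherical permutation: one map's values are rotated over the
   registered sphere (1000 spins by default), preserving spatial
   autocorrelation under the null; within-region correlations over a
   parcellation decompose a cortex-wide r into regional structure via the
   exact identity `Cov_total = Σ_g w_g Cov_within_g + Cov_between`.
5. **Map decomposition** — varimax-rotated PCA of a z-scored vertex × map
   stack, with Tucker congruence coefficients to compare loading patterns.
6. **Allometric scaling** — per-vertex log–log regression of vertex
   surface area on total surface area (slope 1 = isometry), meta-analysed
   across cohorts like any other standardized map.

## Worked example

```python
import dataclasses
import numpy as np
import cortexmeta as cm

mesh = cm.build_icosphere(4)                      # 2562-vertex sphere
config = cm.default_cohort_config(mesh, n_subjects=800, seed=1)

betas, ses = [], []
for i in range(3):                                # three independent cohorts
    cohort = cm.simulate_cohort(mesh, dataclasses.replace(config, seed=1 + i))
    g = cm.OneFactorModel(cohort.test_scores).fit()
    assoc = cm.VertexWiseGLM(
        cohort.morphometry["volume"], g.factor_scores(),
        covariates=cohort.covariates[["age", "sex", "site"]],
        focal_name="g", measure_name="volume",
    ).fit()
    betas.append(assoc.beta_std.values)
    ses.append(assoc.se_std.values)

meta = cm.RandomEffectsMeta(np.stack(betas), np.stack(ses), method="REML").fit()
print(meta.summary())

spins = cm.generate_spins(mesh, n_spins=1000, seed=1)
corr = cm.spin_test(meta.as_maps(mesh.cortex_mask)["beta"],
                    config.effect_map_g, spins)
print(f"recovery: r = {corr.r:.3f}, p_spin = {corr.p_spin:.4f}")
```

Output:

```
One-factor model (casewise ML)
  n subjects: 800   tests: 5
  log-likelihood: -4789.748   chi2(5) = 3.380
  CFI=1.000  TLI=1.005  RMSEA=0.000  SRMR=0.014
  test           loading  uniqueness
  test_0          0.8110      0.3434
  test_1          0.6612      0.5791
  ...

Random-effects meta-analysis (REML), k = 3, 2562 vertex/vertices
  beta: mean = 0.0414, range = [-0.1583, 0.2038]
  tau2: mean = 0.000795; vertices with tau2 > 0: 1377

recovery: r = 0.895, p_spin = 0.0010
```

The fitted loadings track the generating battery (0.8 … 0.4), the pooled
beta map spans the configured effect range, the mean tau² sits near the
configured between-cohort heterogeneity (0.03² = 0.0009), and the pooled
map correlates strongly with the generating effect map at the smallest
attainable spin p (1/1001).

A command-line interface mirrors the stages
(`cortexmeta simulate-mesh | simulate-cohort | gfactor | glm | meta |
smooth | spin-corr | within-region | pca | allometry`); every output is
paired with a JSON provenance sidecar (config echo, seeds, input hashes),
and rerunning a stage with the same configuration reproduces byte-identical
numeric outputs.

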