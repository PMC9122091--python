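# vertexlmm

Mass-univariate vertexwise association mapping for gray-matter-like
feature matrices, contrasting per-vertex general linear models (GLMs) with
linear mixed models (LMMs) that fit *all* vertices as a random effect
through a brain-relatedness matrix (BRM).

## Who this is for

Vertexwise analyses relate a phenotype to hundreds of thousands of
correlated surface measurements (cortical thickness and surface area,
subcortical radial thickness and surface area).  Because vertices
correlate both locally (mesh neighbors) and at long range (head size,
demographics, scanner and other latent factors), per-vertex regressions
can return large smeared clusters and distal false positives.  This
package is for methodologists and imaging statisticians who want to

* run the standard per-vertex GLMs (no covariates; age/sex/ICV; 5/10
  global PCs; 10 per-modality PCs) and their mixed-model counterparts on
  vertexwise matrices,
* estimate *morphometricity* (the phenotypic variance captured jointly by
  all vertices) by REML,
* quantify calibration and discovery — inflation factor, FPR, TPR,
  vertex/cluster FWER, cluster FDR, mapping precision, calibrated power,
  out-of-sample prediction — on simulated phenotypes with known truth.

No real imaging data is required: a synthetic-cohort generator reproduces
the correlation structure the comparison depends on (lattice meshes with
local smoothing, plus partly-hidden latent confounders that induce
long-range and cross-type correlation).

## The models

For standardized vertex `i` the GLM is

    y = Z c + x_i b_i + e,

tested by `chi2_i = (b_i / SE_i)^2 ~ chi2(1)` with Bonferroni correction
across vertices.  The mixed model adds all p vertices as a random effect,

    y = Z c + x_i b_i + X beta + e,     beta ~ N(0, I sigma_b^2),
    var(y) = V = p sigma_b^2 B + sigma_e^2 I,     B = X X' / p,

where `B` is the BRM and `p sigma_b^2 / (p sigma_b^2 + sigma_e^2)` the
morphometricity.  Variance components are estimated once per trait by
average-information REML under the null model; every vertex is then
tested by GLS (`b_i = x_i' P y / x_i' P x_i`, `SE^2 = 1 / x_i' P x_i`).
Conditioning on all vertices removes the signal reachable through other
vertices, which suppresses distal false positives and shrinks clusters.
A third variant fits four random effects, one BRM per measurement type.

## Worked example

```python
import numpy as np
from vertexlmm import (
    GeneratorConfig, ModelSuite, TraitSpec, bonferroni_alpha, build_atlas,
    compute_brm, fit_reml, generate_cohort, simulate_trait,
    standardize_columns, threshold_and_cluster,
)

cfg = GeneratorConfig.desk(N=1000, p=5000, confounder_share=0.3, seed=1)
raw, latent = generate_cohort(cfg)
atlas = build_atlas(cfg)
data = standardize_columns(raw)

# a trait driven by 10 vertices, morphometricity R^2 = 0.20
trait = simulate_trait(data, TraitSpec(10, 0.20, seed=11), atlas)

vc = fit_reml(trait.y, None, [compute_brm(data)])
print(f"morphometricity {vc.morphometricity:.3f} (SE {vc.se_morph:.3f})")

suite = ModelSuite(data, atlas, models=["glm_age_sex_icv", "lmm_global"])
alpha = bonferroni_alpha(data.n_vertices)
for name, res in suite.run(trait.y).items():
    cs = threshold_and_cluster(res, atlas, alpha, trait.causal_ids)
    print(f"{name}: {int((res.pval < alpha).sum())} significant vertices, "
          f"{len(cs)} clusters ({cs.n_tp} TP / {cs.n_fp} FP)")
```

prints

```
morphometricity 0.246 (SE 0.068)
glm_age_sex_icv: 192 significant vertices, 78 clusters (3 TP / 75 FP)
lmm_global: 4 significant vertices, 2 clusters (2 TP / 0 FP)
```

The REML estimate recovers the simulated morphometricity (0.20, here a
draw one SE high).  The covariate-adjusted GLM declares 192 vertices in
78 clusters significant, but 75 of those clusters contain no causal
vertex — null vertices dragged to significance by the latent factors the
age/sex/ICV covariates only partly capture.  The mixed model returns two
small clusters, both true positives: the parsimony that motivates fitting
all vertices as a random effect.  (Replicates vary; averaged over 50
scenario-(ii) traits the pooled cluster FDR is ~0.85 for this GLM and
~0.02 for the LMM.)

A `vertexlmm` command-line tool wraps the same pipeline
(`generate`, `simulate`, `reml`, `assoc`, `metrics`, `predict`,
`experiment`); see `vertexlmm --help`.

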