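# Methods

This note documents the statistical models, the synthetic-data design, the
numerical choices, and the limitations of `vertexlmm`.

## The problem

Vertexwise association mapping relates a phenotype `y` (length N) to each
of p standardized gray-matter measurements `x_i` (cortical thickness,
cortical surface area, subcortical radial thickness, subcortical surface
area, on tessellated meshes).  Vertices are strongly correlated, both
locally (neighboring mesh points) and at long range (head size, demography,
scanner and other subject-level factors load on wide swaths of the
surface).  A per-vertex regression therefore tags not only directly
associated vertices but everything correlated with them, producing smeared
clusters and distal false positives.

## Models

**Mass-univariate GLM.**  For each vertex, OLS of
`y = Z c + x_i b_i + e`, where `Z` is an intercept plus one of five
covariate sets: none; age/sex/ICV; 5 or 10 global principal components of
the vertex matrix; or 10 PCs per measurement type (40 columns).  The test
statistic is `chi2_i = (b_i / SE_i)^2` against chi-square(1).

**BRM mixed model (MOA-style).**  All vertices enter jointly as a random
effect: `y = Z c + x_i b_i + X beta + e` with `beta ~ N(0, I sigma_b^2)`,
giving `var(y) = V = p sigma_b^2 B + sigma_e^2 I` where `B = X X' / p` is
the brain-relatedness matrix.  Because columns are standardized with the
population (1/N) variance, `mean(diag(B)) = 1` exactly and the component
`v = p sigma_b^2` is directly the phenotypic variance share captured by
all vertices (the trait's *morphometricity* `v / (v + sigma_e^2)`).  Three
configurations: a single global BRM; global BRM plus age/sex/ICV fixed
effects; and four random effects, one BRM per measurement type.

**One-pass scanning.**  Variance components are estimated once per trait
under the null model (no candidate fixed effect), then every vertex is
tested by GLS against the resulting `V`:
`b_i = x_i' P y / (x_i' P x_i)`, `SE_i^2 = 1 / (x_i' P x_i)` with
`P = V^-1 - V^-1 Z (Z' V^-1 Z)^-1 Z' V^-1`.  At fixed components this *is*
the per-vertex GLS refit (an identity our tests verify to 1e-8); the
difference from a full per-vertex REML refit is the "double fitting" of
the candidate inside the BRM, which deflates top-vertex chi2 — a one-sided
effect of roughly 5–15% at desk scale (median ~7% in our regime) that
shrinks as per-vertex effects shrink.  The one-pass cost is
O(p N^2 + N^3 + p N) rather than O(p N^3).

**Zero-variance limit.**  When REML pins every BRM component to zero, GLS
with `V = v_e I` reduces to OLS.  We dispatch that case to the OLS engine,
so the degenerate mixed model agrees with the GLM *exactly*, including the
per-vertex residual-variance SE — the natural estimator once no random
effect remains.

## REML

Average-information (AI) REML with:

* parameterization `v_k = p_k sigma_bk^2` attached to mean-diag-1 BRMs
  (numerically stable; components are variance shares);
* initialization at an equal split of var(y) across components + residual;
* an EM step whenever an AI update proposes a negative component, and
  truncation to the zero boundary after two consecutive negative
  proposals (the residual is floored, never pinned);
* convergence when the restricted log-likelihood moves < 1e-8
  (max 100 iterations);
* SEs from the inverse AI matrix; the morphometricity SE by the delta
  method on the ratio (the convention is ours — reference
  implementations report SEs without documenting the method);
* single-BRM models are rotated into the BRM eigenbasis once (O(N^3)),
  after which every REML iteration and every GLS scan is diagonal;
  multi-BRM models use a dense Cholesky per iteration.  Fitting 100
  traits on one N=1000 cohort costs seconds, not hours.

The restricted likelihood includes `-(N - q)/2 log(2 pi)` and the
`log|Z' V^-1 Z|` term; tests pin it against the closed-form i.i.d. value,
a profile-likelihood golden-section oracle, and the balanced one-way
ANOVA intraclass correlation (block BRM).

## Synthetic cohorts

Real vertexwise data is not required; the generator reproduces the two
correlation features the method comparison rests on:

* **meshes** — each measurement type and hemisphere is a 4-neighbor
  lattice (ct/ca 60x75 per hemisphere, st/sa 20x25 by default: p = 20,000
  with the 9:1 cortical:subcortical vertex ratio; presets for p = 5,000
  and 10,000 keep the ratio);
* **local correlation** — the noise field is smoothed on the lattice
  (self-weight 1/2, neighbors share 1/2 equally; 2 rounds by default), a
  graph-native stand-in for a surface FWHM kernel;
* **long-range and cross-type correlation** — K = 6 latent subject
  factors with loading maps that are themselves smoothed lattice noise
  (4 rounds, rows unit-norm), so every factor loads regionally on at
  least two measurement types.  A vertex is
  `sqrt(s) * factors . loadings + sqrt(1-s) * noise` with
  `s = confounder_share = 0.3` by default; two vertices loading on one
  shared factor correlate at `s`.  Three factors are exported as observed
  covariates (age analog; sex analog dichotomized at its median; ICV
  analog) plus pure-noise covariates; the other three stay hidden, so
  covariate-adjusted GLMs remove only part of the confounding.

Replication cohorts reuse the loading maps with fresh subjects; an
optional mean shift on the observed factors emulates a transfer cohort.
What the generator does **not** emulate: real cortical geometry and
mm-scale distances, scanner/site batch structure, non-Gaussian marginals,
and the empirical strength of long-range correlation in real data (no
published estimate exists; `confounder_share` is the knob and 0.3 the
declared study condition).  Passing tests therefore demonstrate the
methods' behavior under this correlation model, not under any particular
scanner's data.

## Phenotype simulation

`m` causal vertices drawn uniformly (optionally within one measurement
type), standard-normal effects, `g = X_causal w`, plus Gaussian noise
scaled so the causal variance share equals the target morphometricity
R^2.  By default (`exact_rescale`) the noise is orthogonalized against
`g` so the realized sample-level share is exact per replicate; the
alternative draws noise at the theoretical variance
`var(g)(1 - R^2)/R^2`.  Scenarios: (i) m=10, R^2=0.20; (ii) m=100,
R^2=0.50; (iii) m=1000, R^2=0.40; 100 replicates each, plus 100 null
traits and per-type restricted variants.

## Evaluation metrics

All computed per replicate and aggregated:

* inflation factor `lambda` = median chi2 on null vertices / 0.4549364
  (the chi-square(1) median), averaged over replicates;
* nominal FPR = share of null vertices with p < 0.05;
* TPR = share of causal vertices significant after Bonferroni;
* vertex / cluster FWER = share of replicates with >= 1 false-positive
  vertex / cluster;
* clusters = connected components of the significant set within one
  structure's mesh graph (never across types, hemispheres or structures);
  a cluster is TP iff it contains a causal vertex (itself significant);
* cluster FDR = FP clusters / all significant clusters, pooled across
  replicates (the per-replicate mean is reported alongside; pooling is
  our choice where the convention is ambiguous), NA when nothing is
  significant;
* mapping precision = median (and max) TP-cluster size;
* calibrated power = TPR at the largest alpha whose cluster FWER <= 0.2,
  found by bisection on log10(alpha) from the Bonferroni threshold
  downward to 0.1-decade resolution.

Thresholding is strict (`p < alpha`); p-values are floored at the
smallest positive double; vertices collinear with the covariates are
flagged and reported as null results rather than raising mid-scan.

## Prediction

Linear scores from significant vertices with marginal weights `b_i`,
either the top vertex per cluster (min p, ties to the lowest id) or all
significant vertices.  Training-cohort standardization is frozen into the
predictor and replayed on test cohorts; test-sample statistics are never
used.  Accuracy is Pearson r with a Fisher-z 95% CI, plus a partial r
after residualizing scores and phenotype on covariates.

At desk scale the "top vertex per cluster beats all-significant" ordering
reproduces decisively for the mixed model (49/50 replicates across
scenarios i and ii) but *not* for confounded GLMs: a GLM's redundant and
false-positive cluster members carry shared-confounder signal that
genuinely predicts in a replication cohort drawn from the same latent
structure, so including them can help.  This is a real property of
confounded marginal weights on matched cohorts, not a defect of the
selection rule.

## Study sizes and known desk-scale deviations

Default experiment sizes are N=1000, p=5000 (calibration and contrast
studies; minutes on one CPU) and N=2000, p=10000 (morphometricity
recovery); the full-resolution setting (N ~ 10^4, p ~ 6.5x10^5) is
cluster-scale by design.  Two behaviors differ from the full-scale
setting and are worth knowing:

* **Bonferroni conservativeness is mild at p=5000.**  On real
  full-resolution meshes the effective number of tests is far below p, so
  the null-trait vertex FWER sits well under the nominal 5%.  On the
  lattice generator with 2-round smoothing the effective test count is
  close to p and the null FWER is ~5% (and the chi-square reference adds
  ~half a point at N=1000 relative to the exact t).  The contrast between
  GLM inflation and LMM control under H1 is unaffected.
* **Double-fitting deflation is visible.**  With p in the thousands the
  candidate vertex is a non-negligible slice of the BRM, so LMM chi2 (and
  lambda ~ 0.92-0.98 under H0) sit slightly below their GLM counterparts;
  this shrinks as p grows.

## Degenerate inputs and tie-breaks

Constant columns are an error naming the vertex ids; empty BRM subsets,
zero-variance phenotypes, rank-deficient covariate designs, and empty
cluster sets (for predictor building) are errors with specific messages;
cluster top-vertex ties break to the lowest id; all randomness flows from
explicit integer seeds (replicate r of a scenario uses
`base_seed + 1000 * scenario_index + r`), and repeated runs with one
config are byte-identical.
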