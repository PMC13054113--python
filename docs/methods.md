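# Methods

`stayblup` implements a single-step genomic evaluation for binary stayability
traits in beef cattle — the probability that a cow stays productive in the
herd to a given age — together with the synthetic populations needed to
exercise it end to end. This note records the models, the numerical choices,
and what the synthetic experiments do and do not demonstrate.

## Traits and data

Stayability is scored per cow as success (2) or failure (1): STAY48-2, for
example, is success when a cow challenged as a heifer has calved at least
twice by 48 months of age; the five definitions combine age limits {48, 54,
72} months with required calvings {2, 3}. Records carry a contemporary group
(CG) label — farm x management group x birth year x birth season (dry
April–September, rainy October–March) — fitted as the only systematic effect.
Genotypes use the BLUPF90-style coding {0, 1, 2, 5 = missing}, one line per
animal with a contiguous code string.

## Relationship matrices

* **A-inverse** comes from Henderson's rules with inbreeding; per-animal
  inbreeding coefficients use the Meuwissen–Luo ancestor-traversal recursion
  (heap-based, with a full-sib cache), so the cost is proportional to total
  ancestry, not pedigree size squared.
* **A22**, the pedigree relationships among genotyped animals, is the
  genotyped block of the tabular A computed on the ancestor closure of the
  genotyped set — never the inverse of a sub-block of A-inverse.
* **G** is VanRaden's first method: codes centered by twice the observed
  allele frequency, missing codes centered to zero (mean imputation), and the
  cross-product divided by `2 Σ p_j (1 − p_j)`. G is then *tuned* (mean
  diagonal and mean off-diagonal matched to A22 by solving the 2x2 linear
  system for `a + bG`) and *blended* (`0.95 G + 0.05 A22`). Tuning precedes
  blending so that the blending step is the positive-definiteness guarantee.
* **G-inverse** is a dense Cholesky inverse, or the APY recursion on a core
  subset. APY treats non-core animals as conditionally independent given the
  core; its inverse is exact under exactly that structure, which is also the
  structure our correctness fixtures use. A warning from development: a
  "low-rank plus small ridge" G does **not** approach APY's assumption — the
  conditional correlations among non-core animals stay O(1) as the ridge
  shrinks — so closeness to the dense inverse must not be tested that way.
* **H-inverse** adds `G⁻¹ − A22⁻¹` to the genotyped block of A-inverse; it is
  exposed as an operator (matvec/diagonal/sparse materialization) so solvers
  never need dense H.

## Genotype quality control

Filters run in a fixed order (sample call rate 0.90; marker call rate 0.90;
sex/mitochondrial chromosomes; duplicate map positions, keeping the best call
rate; Mendelian conflicts — opposing homozygotes against a genotyped parent —
above 1%; MAF below 0.05; Hardy–Weinberg chi-square p < 1e-10). All marker
statistics are computed on the sample-filtered matrix before any marker is
removed, so the retained set is order-independent even though per-filter
attribution is not. Thresholds are strict inequalities: a marker at exactly
MAF 0.05 survives.

## Linear model

`y = Xβ + Zu + e`, `u ~ (0, H σ²ᵤ)`, with the score kept on its {1, 2}
coding (breeding values are translation invariant). The mixed-model equations
are solved by conjugate gradients with a Jacobi preconditioner to a relative
residual of 1e-12; a dense direct solve backs the tests. The variance ratio
for the observed-scale linear model comes from the liability-scale components
passed through the scale transformation below — the same policy as routine
two-stage evaluations.

## Threshold model and Gibbs sampler

The threshold model places a unit-variance normal liability behind each
record (threshold 0, residual variance 1 — the standard identification).
Each sweep: (1) liabilities drawn from normals truncated to the record's
category side, via the inverse-CDF in log space
(`ndtri_exp(log_ndtr(·) + log U)`), which keeps full precision arbitrarily
far into the tails; (2) CG effects and breeding values updated by
systematic-scan single-site draws over the MME system (a numba kernel;
a blocked dense-Cholesky joint draw is available for systems up to order
4000 and backs the correctness tests); (3) the additive variance drawn from
its scaled inverse chi-square conditional. Running means of the scan
conditional means (Rao-Blackwellized) give the reported GEBV; thinned
post-burn-in samples give the posterior summaries (mean, SD, shortest-window
95% HPD) and the Geweke diagnostic (first 10% vs last 50%, segment-mean
variances by non-overlapping batch means with cube-root batch size — accurate
for the thinned, weakly autocorrelated chains the sampler stores).

**Variance prior.** The additive-variance prior defaults to a proper, weakly
informative scaled inverse chi-square with ν = 4 and S = 0.25 (prior mean 0.5
liability units, weight equivalent to four records). A flat prior (ν = −2,
S = 0) is configurable but **improper for binary data**: because the fixed
effects can rescale with σᵤ, the marginal likelihood of a threshold animal
model tends to a positive constant as σ²ᵤ → ∞, so a flat prior puts infinite
mass in the tail. At desk-scale data sizes (10³–10⁴ records) chains
demonstrably escape within a few thousand sweeps — we confirmed the escape
with an exact blocked sampler and by GHK integration of the marginal
likelihood on a small pedigree (decay of only ~1 nat per doubling of σ²ᵤ past
the mode). National-scale analyses do not notice this because their interior
mode towers over the tail for any feasible chain length.

**Two-stage evaluation.** Following routine practice, validation experiments
estimate variance components once on the whole data and then solve the
threshold model with the components *fixed* (`fix_variances=True`) on both
whole and partial data. Re-estimating components inside each fit leaves the
two predictions on slightly different shrinkage scales and systematically
depresses the LR dispersion statistic (we measured b₁ ≈ 0.7 with one-stage
fits versus ≈ 1.0 with the two-stage policy, with Monte-Carlo noise ruled out
by a two-chain reliability of 0.99).

**Which chain estimates the components.** Even with the proper prior, the
threshold-mode σ²ᵤ chain needs an information-rich design to stay anchored
at desk scale: single-sex phenotyping with many unphenotyped relatives and a
modest record count leaves the heavy posterior tail within reach of a few
thousand sweeps (the pipeline's Geweke table flags exactly this when it
happens). The end-to-end pipeline therefore estimates components with the
*linear-mode* chain on the coded scores — stable at any of these sizes —
and converts them to the liability scale through the inverse Dempster–Lerner
map (the transformation's classical use), then solves the threshold model
with the converted components fixed. Threshold-mode variance estimation
remains available (and is what the recovery experiments validate, on their
all-phenotyped design). If the converted heritability leaves (0, 1) — which
can happen for strongly familial composite scores in small samples — the
pipeline caps it at 0.9 and logs the cap.

## Scale transformation

With success incidence α, threshold t = Φ⁻¹(1 − α) and z = φ(t):
`h²_obs = z² h²_lia / (α(1−α))`, `σ²ᵤ_obs = z² h²_lia`, `σ²ₚ_obs = α(1−α)`,
and `σ²ₑ_obs = σ²ₚ_obs − (σ²ᵤ_obs + σ²_pe + σ²_cg)` with the last two zero
for single-record stayability. The residual formula subtracts *all*
non-residual components together — the grouping matters and is the only
reading that reproduces the published observed-scale tables. The conversion
is symmetric in α and 1 − α and maximal at α = 0.5, where
`h²_obs = (2/π) h²_lia`.

## LR validation

The partial dataset removes the last two years of records by record year;
focal animals are genotyped females whose own record was removed and whose
progeny have no partial records. Statistics on focal animals
(sample moments, denominator n − 1):

* accuracy `acc = sqrt(cov(û_w, û_p) / ((1 − F̄) σ̂²ᵤ))`,
* bias `δ = (mean(û_p) − mean(û_w)) / σ̂ᵤ`,
* dispersion `b₁ = cov(û_w, û_p) / var(û_p)` (1 is ideal),
* correlation `corr = cov / sqrt(var(û_w) var(û_p))`,

with F̄ the focal animals' mean pedigree inbreeding and σ̂²ᵤ the whole-data
estimate on the scale of the model being validated. The accuracy takes the
square root of the covariance ratio — the LR method's definition — and is
floored at zero (with a warning) if the covariance is negative.

## Synthetic populations

The generator produces discrete generations of constant size with a
restricted sire pool (8% of males), multinomial farm/management assignment,
and birth years spread across the configured range. Genotypes are gene-dropped
from Hardy–Weinberg founders (frequencies uniform on the configured MAF
range). True breeding values are built from marker effects,
`u = Z α`, `α_j ~ N(0, σ²ᵤ / Σ 2p_j(1−p_j))`, so genomic information is
genuinely predictive; CG effects are normal with variance 0.1. The liability
convention is σ²ₑ = 1 and σ²ᵤ = h²/(1 − h²).

Calving histories place breeding opportunities on a 12-month grid from a
first exposure at 10–14 months with a fixed 9-month gestation; conception at
opportunity k is the indicator `μ_k + u_i + cg_i + ε_ik > 0` with μ_k set by
probit from the per-opportunity base rate. The default rates
(0.17, 0.19, 0.26, 0.68, 0.76) were calibrated once by Monte Carlo so the
realized STAY48-2 incidence sits near the ~14% reported for Nellore herds;
STAY72-3 lands near 33%. What the generator does **not** emulate: culling
(a failed female stays exposed), so successive calvings are less correlated
than in real herds and the three-of-three definitions (STAY48-3) come out
rarer (~3%) than the published 13%; no selection, no missing pedigree links,
no genotyping error. Passing tests therefore demonstrate internal
consistency of the estimation machinery under the model's own assumptions,
not robustness to the selection and data-quality artifacts of field data.

A single-opportunity special case (`simulate_threshold_phenotype`) yields a
binary trait that follows the threshold model *exactly* — unlike the
composite STAY scores, which are "at least k successes of m correlated
probit events" and have no single liability representation. Recovery and
LR-calibration experiments use this trait, optionally scored on all animals
rather than females only, which maximizes the information about σ²ᵤ at desk
scale.

## Problem sizes and experiment designs

* Heritability recovery: five populations of 5,000 animals (4 generations of
  1,250; every animal scored; incidence 0.15; ~25 large CGs), pedigree-only
  relationships, chains of 20,000 sweeps (burn-in 6,000, thin 10), h²ₗ
  alternating between 0.16 and 0.22. Success criterion: truth inside the 95%
  HPD in at least 4 of 5.
* LR calibration: five populations of 4,800 animals, h²ₗ = 0.22, incidence
  0.38, genotyped set = last generation's females (~600 focal animals, 1,000
  SNPs), two-year truncation; a 6,000-sweep variance chain and
  fixed-variance solves. Bounds: mean threshold b₁ in [0.8, 1.2], |mean δ| ≤
  0.1, mean threshold/linear focal-GEBV correlation > 0.9.
* The default pipeline run: 3,200 animals (4 generations of 800), 2,000
  SNPs, half the population genotyped, 4,000-sweep chains; end to end in
  about 1.5 minutes.

These sizes are the package's chosen desk-scale study conditions; all
experiments are seeded and reproduce bit-for-bit.

## Known limitations

* Single trait, single fixed factor (CG); no permanent-environment or
  maternal effects, matching the stayability model.
* The threshold sampler is single-site; posterior autocorrelation for σ²ᵤ is
  substantial, and short chains are only adequate for GEBV means, not for
  variance inference.
* APY core selection is uniformly random; no dimensionality-based choice.
* The Geweke batch-means variance estimate assumes modest autocorrelation;
  apply it to thinned chains.
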