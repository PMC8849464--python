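# Methods

`landgen` implements a landscape-genomics workflow for a Chagas-disease
vector sampled from domestic and wild (sylvatic) ecotopes across a
mountainous study region: population-genetic differentiation statistics, a
multi-method scan for domestically-associated outlier loci,
isolation-by-distance regressions with an MLPE correlation structure, and
resistance-surface optimisation with commute-time effective distances,
AICc model selection and circuit-theory connectivity mapping. Because no
machine-readable genotype deposit exists at desk scale, every stage is
exercised against a bundled synthetic-data generator with known ground
truth; this note records the models, the defaults, and what the synthetic
checks do and do not demonstrate.

## Synthetic data generator

**Landscape.** Elevation is a stationary Gaussian random field with
exponential covariance `exp(-h/range)`, simulated by circulant embedding on
a doubled torus (negative embedding eigenvalues, possible for this kernel on
small grids, are clipped to zero; the clipping slightly inflates marginal
variance at short ranges, which the variogram test tolerates). The
unit-variance field z maps to elevation `1500 + 500 z` m, clipped to
[0, 3000]. A fixed affine map is used rather than min-max rescaling so that
a long-range (spatially flat) field stays flat instead of being stretched to
the full range. Default grid 60x60 cells of 250 m; default range 3 km.

**Sites.** Random cell centres with a minimum pairwise separation (default
1 km), placed by bounded rejection sampling. Default 25 sites, 7 of which
carry both a domestic and a wild group ("dual" sites, matching the study
design emulated); the remainder alternate domestic-only/wild-only. Each
group holds 10 diploid samples by default.

**Genotypes: Gaussian-copula Beta model.** Per locus, an ancestral
frequency p0 ~ Beta(2, 2); a latent site vector z ~ MVN with correlation
`exp(-d_eff/lambda)`, where d_eff is the commute-time effective distance
under the true resistance surface and lambda defaults to the median
off-diagonal d_eff (a scale at which spatial correlation is informative for
any commute-time magnitude). Each z is pushed through the standard-normal
CDF into the quantile of the Balding-Nichols marginal
Beta(p0(1-F)/F, (1-p0)(1-F)/F), so site frequencies keep F-model marginals
(the ones assumed by F_ST-outlier theory) while gaining spatial correlation
that decays with resistance distance. With spatially uncorrelated sites the
realised multilocus Weir-Cockerham theta equals the nominal F (verified
against a brute-force independent simulator); with correlated sites the
realised among-site variance is smaller than F by roughly the mean
between-site correlation — differentiation statistics measure variance
*among* the sampled sites, not around the ancestral frequency.

Outlier loci (default 5 of 2,500) add a logit-scale shift delta (default 2)
to every domestic group's frequency; delta is a free simulation knob — the
study this emulates provides no effect-size estimate for domestic
adaptation. Genotypes are Binomial(2, p) per individual (Hardy-Weinberg
within groups, no inbreeding); missingness is completely at random (default
0.5%). Deterministic given the seed: one global seed expands into per-stage
substreams by hashing a stage label into the SeedSequence entropy pool.

What the generator does **not** emulate: linkage between loci, genotyping
error and allelic dropout, non-equilibrium demography (bottlenecks,
admixture), sex-biased dispersal, or temporal structure beyond a random
collection-year label. Passing tests therefore demonstrate estimator and
pipeline correctness under an idealised spatial F-model, not robustness to
those real-data features.

## Population-genetic statistics

All statistics use pairwise-complete observations per locus; loci with
fewer than two called genotypes in a group are skipped for that group.

* **Diversity**: observed heterozygosity H_O; Nei's unbiased gene diversity
  H_E with the 2n/(2n-1) correction; F_IS = 1 - H_O/H_E on the multilocus
  averages (0 when H_E = 0).
* **Rarefied allelic richness**: A_r = sum over alleles of
  [1 - C(N-N_i, g)/C(N, g)] at g gene copies (default: the smallest
  per-locus gene-copy count in any group), averaged over loci. Group
  contrasts use a two-sided permutation two-sample test on per-locus values
  (10,000 permutations, p = (b+1)/(B+1)).
* **LD**: composite (Burrows) r-squared as the squared Pearson correlation
  of genotype codes; monomorphic pairs excluded and counted.
* **Pairwise Nei (1973) F_ST** = (H_T - H_S)/H_T from multilocus averaged
  heterozygosities (unbiased H_S, plain H_T), significance by reshuffling
  individuals between the two groups (999 permutations), Benjamini-Hochberg
  FDR across pairs.
* **G''_ST and F'_ST**: Nei & Chesser (1983) estimators (harmonic-mean
  sample size, H_O correction) feed the double-corrected G''_ST of Meirmans
  & Hedrick (2011) and the maximum-standardised F'_ST (F_ST divided by its
  value after recoding every allele as private to its population).
* **Hierarchical F-statistics**: allele-level nested ANOVA
  (method-of-moments, unbalanced-design coefficients) with strata
  site / optional inner level (ecotope or year) / individual / allele.
  Summed per-locus components give F ratios; collapsed to sites-only this is
  exactly Weir-Cockerham theta (tested to 1e-10 against a brute-force
  implementation). 95% CIs bootstrap loci; significance permutes the units
  one level below the tested level (individuals are never split).

## Outlier scans

Four scans over a common locus universe, plus their consensus
(intersections at >= 1, 2, 3, all methods):

* **Random forest**: bagged decision trees (sqrt-features per split,
  class-balanced weights). Importance is the per-tree out-of-bag
  permutation accuracy decrease, scaled by its standard error over trees
  (the classic randomForest `scale=TRUE` convention) and averaged over
  three independent runs whose pairwise Pearson correlation is reported as
  a convergence check (warning below mean r = 0.5). Spatial structure is
  removed by residualising genotypes on the first three principal
  coordinates of the inter-sample geographic distance matrix (config
  switch: `residualise` | `covariates` | `off`). Loci with mean scaled
  importance > 3 enter backwards purging: refit, drop the least important
  locus, repeat down to two, return the subset with the lowest out-of-bag
  error (ties to the smaller subset). Desk default 1,000-5,000 trees
  (overridable); the scaled-importance magnitude depends on tree count, so
  the threshold of 3 is calibrated for a few hundred trees and up.
* **Partial RDA**: genotypes (per-locus mean-imputed, centred) and the
  ecotope indicator are residualised on the spatial principal coordinates;
  with one binary predictor the constrained ordination has a single axis
  whose per-locus loadings are the regression coefficients, z-scored and
  flagged at |z| > 2 and > 3 SD. Significance: pseudo-F with the
  residualised predictor permuted (999 permutations).
* **OutFlank-style scan**: per-locus uncorrected F_ST (weighted variance of
  group frequencies over pbar qbar). The lowest 6% and highest 35% of
  values are trimmed and a scaled chi-square (df, mean) is fitted by
  maximum likelihood to the retained, *truncated* distribution (Brent
  search on df in (1, 200), mean profiled). Loci with pooled
  heterozygosity >= 0.1 get right-tail p and BH q; flags at q < 0.05.
  Low-heterozygosity loci are never flagged.
* **fsthet-style scan**: 10 equal-count heterozygosity bins, per-bin
  alpha/2 and 1-alpha/2 empirical F_ST quantiles smoothed by a 3-bin moving
  average and interpolated at each locus's heterozygosity; distribution-free
  envelope flags. The envelope is forced non-crossing.

Null calibration (delta = 0, 25 sites, F = 0.1): OutFlank flags well below
q_cut (the trimmed-truncated fit is conservative), fsthet flags ~ alpha,
RDA two-sided 2 SD flags ~ 4.6%. The >= 3-method consensus trades recall
for precision and beats every single method's precision on injected-locus
recovery.

## MLPE isolation-by-distance

Pairwise genetic distance is regressed on centred predictor distance with
an optional ecotope stratum main effect and stratum-by-distance
interaction. The covariance is `sigma_e^2 I + sigma_u^2 Z Z'` with Z the
pair-population incidence matrix; two pairs sharing one population have
correlation rho = gamma/(2 gamma + 1) in [0, 0.5) with
gamma = sigma_u^2/sigma_e^2. gamma is profiled by golden-section search on
log gamma in [1e-8, 1e3] (tolerance 1e-8); gamma = 0 is evaluated
explicitly so the fit reduces exactly to OLS for independent pairs. All
fits are maximum likelihood (not REML) so log-likelihoods are comparable
across fixed-effect structures and usable as the GA objective and in AICc.
Centring the predictor decorrelates intercept and slope estimates (exact:
adding a constant to all distances leaves the slope unchanged to 1e-10).
The slope contrast between ecotopes is a Wald test on the interaction
coefficient, with an optional 1-df likelihood-ratio test against the
no-interaction model. Mantel tests (default 9,999 permutations, one-sided)
accompany the parametric fits. Both a joint two-stratum model and separate
per-stratum fits are possible; the joint model is the primary interface
because the reported contrast is a single coefficient with a standard
error.

## Resistance surfaces and connectivity

Surfaces are rescaled to [1, 100]. Continuous surfaces are transformed by a
monomolecular family R(x) = 1 + (m-1) g(x') with x' = (x-1)/99 and g a
saturating curve `(1-exp(-u/s))/(1-exp(-1/s))`; three binary switches
(reverse input, flip output, inverse curve) give 8 distinct shapes —
a documented superset of the admissible transformations in the emulated
workflow, whose exact variant list is unpublished. Categorical surfaces get
per-class resistance values in [1, 100] with the least-resistance anchor
class fixed at 1 (removes scale unidentifiability). Surface collinearity is
screened by Spearman rho with a warning at |rho| >= 0.29.

The resistance raster defines a conductance graph: 8-neighbour
connectivity, edge resistance = mean of the two cell resistances (diagonals
scaled by sqrt 2), conductance the reciprocal. Effective distance is the
random-walk commute time C(i,j) = vol(G) R_eff(i,j), with R_eff from the
reduced (grounded) Laplacian solved by sparse LU; the current mapper solves
per-pair potentials from the same factorisation, checks Kirchhoff
conservation, and accumulates half the absolute incident edge current per
cell. Note that commute time is invariant to a common factor on all
resistances (the walk's transition probabilities are scale-free) while
R_eff scales linearly — model ranking is additionally protected by
z-scoring the predictor before the MLPE fit.

**Optimisation**: a real-coded GA (population = pop_mult x genome length,
pop_mult 20 by default; tournament selection of 3, BLX crossover, Gaussian
mutation, elitism of one, deterministic per seed) maximises the MLPE
log-likelihood of genetic distance on the standardised commute distances.
Composite surfaces sum component resistances cell-wise and re-anchor the
minimum to 1 (the combination rule is not published; summation is the
simplest order-independent choice). Parameter counts follow the printed
accounting: k = 2 + (surface parameters) for single surfaces (shape+max
continuous, classes-1 categorical), composites sum single-surface k's minus
the shared intercepts; distance-only k = 2, null k = 1.

**Selection**: AICc = -2 logLik + 2k + 2k(k+1)/(n-k-1) with n = number of
sites by default (`aicc_n: sites|pairs` is exposed because conventions
differ in the literature; n = sites is consistent with the printed k = 20
model at 25 sites). Akaike weights normalise exp(-delta/2). Robustness:
site bootstrap (default 85% of sites per iteration, surface parameters
frozen at their full-data optima — re-optimising inside thousands of
iterations is both infeasible and unlike the emulated procedure), reporting
average AICc, average rank and top-model percentage.

## Problem sizes in tests and the acceptance script

Simulation-heavy checks run at reduced sizes chosen as package defaults:
40x40 rasters (10 km extent at 250 m cells), 12-25 sites, 200-1,000 loci,
GA populations of 30 with <= 12 generations, 12-20 replicates per check,
and 200 replicates for MLPE coverage. The landscape-recovery scenario uses
a landscape-scale elevation gradient (field range 8 km, monomolecular truth
shape 0.5, maximum 100, baseline F = 0.2): with short-range terrain the
commute distances under the true surface and under a uniform surface are
nearly collinear (r ~ 0.98), and no method — not even the true
parameters — can overcome the AICc penalty against the 2-parameter
distance model; a smooth regional gradient is both realistic for an Andean
study area and statistically identifiable. The same tension (elevation
narrowly beating plain distance, and losing to it in bootstrap
subsamples) is the central model-selection result of the emulated study.

## Numerical choices

* Correlation matrices get a 1e-8 diagonal jitter before Cholesky; failure
  after jitter is a simulation error.
* Permutation p-values always use (b+1)/(B+1); BH-FDR for multiplicity.
* Golden-section searches: variance ratio tolerance 1e-8 (log scale).
* The truncated chi-square fit rejects non-positive F_ST values and errors
  if fewer than 10 fitting loci remain.
* Rarefaction uses log-gamma binomial ratios for numerical stability.
* Monomorphic or H_T = 0 pairs report differentiation 0 by convention.
* GA continuous shape is searched on the log scale in [0.05, 10].

## Known limitations

* The RF balanced-class handling uses class weights, not per-tree
  stratified subsampling.
* The fsthet envelope inherits edge bias from interpolating bin-centre
  quantiles; its realised null flag rate runs ~1 percentage point above
  alpha.
* Hierarchical F permutation tests permute individuals (not whole
  subgroups) within the parent stratum.
* No reprojection: rasters and coordinates must be pre-projected and
  co-registered. Raster I/O is ESRI ASCII grid only.
* Commute-time computations assume the valid-cell graph restricted to the
  focal component; isolated focal sites are an error, not an imputation.
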