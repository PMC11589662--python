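# Methods

`pairflow` implements a comparative framework for asking what predicts gene
flow between closely related lineages: given many geographically adjacent
pairs of populations or species, it estimates per-pair gene flow from
genotype clustering, quantifies how much the members of each pair differ in
phenotype, climatic niche, age and geography, and asks which of those four
axes of divergence best explains the variation in gene flow. The reference
application is a clade of *Sceloporus* spiny lizards from northeastern
Mexico with 21 lineage pairs; the packaged comparison table for that system
ships with the library and drives the reproduction tests.

## Gene-flow statistics

Gene flow between the two lineages of a pair is summarised from a
cluster-assignment matrix **Q** (individuals × K clusters, rows summing
to 1). After associating each lineage (clade) with one cluster — using the
individuals assigned with ≥ 0.999 probability, falling back to the highest
clade-mean assignment when no individual is that clean — two statistics are
computed over all individuals of both clades:

* **Mean admixture frequency**: the average assignment probability to the
  *other* clade's cluster, reported as a percentage (0–100). This is the
  response variable of the regression stage.
* **Proportion admixed**: the fraction of individuals whose other-clade
  probability is nonzero after rounding to three decimals. The rounding
  threshold (`zero_decimals=3`) matches the precision at which clustering
  programs report assignment probabilities; "nonzero" at full float
  precision would be meaningless.

When a comparison requires K = 3 clusters (both lineages partially
assigned to a third cluster), the statistics are computed on the two
clusters that correspond to the clades. The third cluster's probability
mass is *ignored*, not renormalised, by default; `renormalize=True` divides
by the mass on the two mapped clusters instead. Either convention is
defensible; ignoring is the default because it never inflates an
individual's apparent admixture.

Q-matrices can be imported from clustering-program output files
(`pairflow.io.read_qmatrix`) or estimated internally.

## Admixture estimation (EM)

`fit_admixture` maximises the standard admixture likelihood

    L = Σ_ij [ g_ij log f_ij + (2 − g_ij) log(1 − f_ij) ],
    f_ij = Σ_k q_ik p_kj

over ancestry proportions Q and cluster allele frequencies P by
expectation–maximisation, with multiple restarts (default 5) from seeds
derived deterministically from one master seed; the best likelihood wins,
ties broken by lowest restart index. Missing genotypes contribute nothing.
The log-likelihood is checked to be nondecreasing at every iteration;
allele frequencies are clamped to [1e-6, 1 − 1e-6]. This is a
maximum-likelihood counterpart of the Bayesian MCMC clustering commonly
used for this task: the downstream statistics are functions of Q only, so
any estimator of Q (or an imported Q-matrix) can stand behind them.

Two estimator properties matter for interpretation:

* With ~10 individuals per cluster, the joint MLE absorbs admixture that is
  *shared uniformly* across all individuals of a cluster into that
  cluster's allele frequencies, biasing such Q rows toward one-hot. When
  admixture is concentrated in a subset of individuals (the typical
  empirical pattern, and the synthetic default) this bias is small.
* Cluster labels are arbitrary; comparisons against a reference Q-matrix
  must first align columns (`align_q_columns`, Hungarian assignment).

`choose_k` selects the number of clusters by k-means BIC
(`n log(WSS/n) + k log n`) on leading genotype PCs, mirroring the
ordination-based model selection widely used for RADseq data.

## SNP filtering

`filter_snps` retains biallelic sites that are (i) called in at least 50%
of individuals, (ii) have QUAL ≥ 30 and (iii) a minor allele count ≥ 3
among non-missing calls (heterozygotes contribute one alternate allele; the
boundary is inclusive). Sites lacking a QUAL value fail the quality filter
unless explicitly permitted — the conservative choice. The three criteria
are evaluated per site on the same input, so filtering is idempotent and
order-independent. Upstream assembly-level screens (per-tag coverage,
tag-sharing thresholds) are assumed already applied to the input VCF.

## PC-weighted divergence

Morphological and climatic divergence between two units uses the principal
components of the trait matrix. With x_k, y_k the two units' scores on PC
k, z_k the percentage of variance explained by that PC, and m the smallest
number of leading PCs cumulatively explaining ≥ 99% of variance
(inclusive boundary),

    D = (1/m) Σ_{k=1..m} |x_k − y_k| · z_k.

Notes on conventions:

* The absolute value per PC is deliberate: a signed sum would change with
  arbitrary PC orientations and could cancel; divergence must be
  nonnegative and zero only for identical retained-score profiles. D is
  symmetric and satisfies the triangle inequality on the z-weighted score
  space.
* z stays on the percentage (0–100) scale and the divisor is the retained
  count m, matching the magnitudes of the reference system's published
  values (morphology up to ~15, climate up to ~104).
* PCA is covariance-based (columns centred, not scaled) by default. Bioclim
  variables have wildly different numeric ranges, and an unscaled climate
  PCA dominated by one axis (>80% on PC1) is the signature pattern of such
  data; a `scale=True` flag runs the correlation-matrix analysis instead
  and errors on zero-variance variables by name.
* Climate is recorded per locality; locality rows are averaged into units
  (arithmetic mean per variable) before ordination.

Genotype-space ordination (`genotype_pca`) mean-imputes missing calls per
site, drops fully missing sites, and is otherwise the same engine. Mean
imputation shrinks high-missingness individuals toward the origin, which is
why per-sample missingness is rank-correlated against the first three PC
scores (`missingness_pc_correlation`) as a standard diagnostic; constant
inputs are flagged degenerate (rho 0, p 1) rather than erroring.

Species delimitation is dual-criterion: a candidate species must (1) have
every individual assigned with > 90% probability to one common cluster not
claimed by outsiders (`delimit_by_assignment`), and (2) occupy a distinct
region of genotype PC space (`delimit_by_ordination`), operationalised as
every individual lying strictly closer to its own group centroid than to
the other group's in the first three PCs. The centroid rule is a
deterministic, testable proxy for the visual judgement usually applied to
3-PC scatter plots.

## Geography and time

Great-circle distances use the haversine formula on a sphere of radius
6378.137 km (the default of the common geospatial R package; a flag allows
6371.0088). Unit coordinates are the arithmetic mean of member latitudes
and longitudes — not a true spherical centroid, and without antimeridian
handling; both simplifications are harmless at the regional (tens to
hundreds of km) scale targeted. Divergence times are consumed as inputs in
Myr; an optional reader extracts MRCA ages from an ultrametric Newick tree.

## Regression stage

Rank correlations among the pair-table columns use tie-corrected Spearman
rho (Pearson correlation of average ranks) with the t-approximation
p-value on n − 2 degrees of freedom; constant inputs are flagged
degenerate.

The gene-flow response (clade-based mean admixture frequency, kept on the
0–100 scale) is modelled with Gaussian-error Bayesian linear models:

* flat (improper uniform) prior on coefficients;
* inverse-gamma IG(nu/2, nu·V/2) with nu = 0.002, V = 1 on the residual
  variance — the conventional weakly informative default of the MCMCglmm
  family this mirrors;
* chains of 1,000,000 iterations, burn-in 1,000, thinning 200 → 4,995
  retained samples; convergence bar ESS > 3,000.

Sampling is two-block Gibbs. Because the coefficient prior is flat,
β | σ² = β̂ + σ L z with L the Cholesky factor of (X'X)⁻¹ and z standard
normal, and the residual sum of squares at the drawn β is
SSR_min + σ²‖z‖². The σ² chain therefore reduces to an exact scalar
recursion over predrawn Gamma and ‖z‖² variates, with coefficient draws
reconstructed only at retained iterations — identical in distribution to
the naive sampler at a fraction of the cost (~0.5 s per million-iteration
model). Identical seeds give identical chains.

Reported per coefficient: posterior mean, 95% credible interval, ESS
(autocorrelation-time estimator), and pMCMC = max(2/n_samples,
2·min(Pr(β>0), Pr(β<0))). Model support uses DIC in the Spiegelhalter
form, 2·mean(deviance) − deviance(posterior means), with Gaussian
deviance −2 log L; an exact-fit design (residual variance < 1e-12) is
rejected rather than reporting a divergent DIC. The default comparison set
is the 14 models of the reference analysis — every nonempty subset of
{time, space, morphology, climate} except time + morphology + climate,
which that analysis omitted; `include_all15` restores it. Rankings report
delta-DIC with the usual bands (< 2 considerable support, > 3 far less).

Predictors enter untransformed and unstandardised by default (a
`standardize` flag exists for sensitivity runs), and the response is a
bounded, zero-inflated percentage modelled with Gaussian errors — a known
simplification of the replicated design, kept deliberately rather than
"improved", since the reproduction target is the published analysis.
Sensitivity re-runs are expressed as row-exclusion lists over comparison
ids.

Intra- vs interspecific contrasts label each pair by mapping its two clades
through a species map and report per-group count, median and interquartile
range for all four admixture columns.

## Synthetic data

The generator produces data with the statistical structure the analysis
assumes, with known truth:

* **Genotypes.** Per site, an ancestral frequency p ~ Uniform(0.05, 0.95);
  per cluster, a Balding–Nichols draw Beta(p(1−F)/F, (1−p)(1−F)/F) with
  F = `allele_freq_divergence` (default 0.25 — strong differentiation, as
  expected for lineages a few Myr diverged whose empirical clustering
  yields near-100% assignments). Ancestry rows: a fraction
  `admixed_fraction` (default 0.5) of individuals draw Dirichlet rows with
  expected minor mass `admixture_level`/`admixed_fraction`; the rest are
  exact one-hot, so the population-level expected minor ancestry is
  `admixture_level` (default 0.05, the low-gene-flow regime typical of the
  reference system). Concentrating admixture in a subset matches the
  empirical pattern (most individuals show 0%) and keeps the truth
  identifiable by the EM estimator (see above). Genotypes are
  Binomial(2, q·p) with i.i.d. (MCAR) missingness at `missing_rate`
  (default 0.1, a post-filter scale).
* **Traits/climate.** Per-clade trait centroids separated by
  `trait_divergence` along random directions over unit-scale noise
  (42 characters by default); 19 climate variables from a rank-2 factor
  model plus small noise, so 2 PCs carry > 90% of variance. Clade centres
  sit ~1 degree apart near 24° N, 100° W, giving pairwise distances of
  roughly 50–250 km for adjacent clades.

Defaults: 2 clusters × 10 individuals × 2000 sites — the per-comparison
scale of the reference system and the scale at which the test suite's
recovery bars (aligned-Q RMSE < 0.05; pair-level mean admixture within
0.03 of the realised truth) are calibrated.

What the generator does **not** emulate: linkage (sites are independent),
structured missingness (real RADseq missingness is lineage-correlated;
MCAR suffices to exercise the missingness–PC diagnostic but not to
reproduce its empirical bias patterns), genotyping error, and any
read-level process. Passing tests therefore demonstrate correctness of the
statistics and estimators under the assumed model, not robustness to those
real-data complications.

## Known limitations and numerical choices

* Tests and reproduction runs that involve the packaged comparison table
  inherit its printed precision: columns are rounded as published (times
  to 2 decimals, PC divergences to 1), which creates tie groups the
  original unrounded data did not have. Two of the nine published rank
  correlations (those involving divergence time) and one sensitivity
  result (morphology significance after dropping four comparisons) are not
  recoverable exactly from the rounded table; the corresponding tests
  document this by failing against the published values while the
  underlying computation is verified against independent oracles.
* The EM estimator's shared-admixture bias (above) means pair-level mean
  admixture is conservatively estimated when admixture is uniform across
  individuals.
* "100% assignment" is operationalised as ≥ 0.999; exact 1.0 is not
  reliably printed by clustering software.
* `retain_pcs` treats the 99% boundary inclusively with a 1e-9 float
  tolerance; `filter_snps` boundaries are inclusive; DIC requires a
  non-degenerate residual (error below 1e-12).
* Spearman p-values use the t-approximation, adequate at n ≥ ~10; the
  constant-vector case returns a flagged (0, 1) rather than NaN.
* Longitude averaging and haversine assume no antimeridian crossing.
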