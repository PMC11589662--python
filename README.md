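# pairflow

**What predicts gene flow between diverging lineages?** `pairflow` is a
Python toolkit for comparative analyses that relate per-pair gene flow —
estimated from genotype clustering — to four candidate predictors:
divergence time, geographic distance, morphological divergence and
climatic-niche divergence. It was built around a study system of
*Sceloporus* spiny lizards from northeastern Mexico (21 pairs of
geographically adjacent clades spanning intra- to interspecific
divergence), whose published comparison table ships with the package, but
every stage works on user data or on the bundled synthetic-data generator.

It is aimed at population geneticists and speciation biologists with
RADseq-style SNP matrices who want a reproducible, scriptable version of
the familiar STRUCTURE-plus-GLM workflow.

## The statistics at its core

**Gene flow between a pair of lineages** is summarised from a
cluster-assignment matrix Q (individuals × K, rows sum to 1). With each
clade associated to one cluster, the *mean admixture frequency* is the
average assignment probability to the other clade's cluster across all
individuals of both clades (in percent), and the *proportion admixed* is
the fraction of individuals whose other-clade probability is nonzero at
3-decimal reporting precision. Q-matrices can be imported or estimated
internally by EM on the standard admixture likelihood
L = Σ g log f + (2−g) log(1−f), f_ij = Σ_k q_ik p_kj.

**Divergence in morphology or climate** between units x and y is
PC-weighted:

    D = (1/m) · Σ_{k=1..m} |x_k − y_k| · z_k

over the m principal components cumulatively explaining ≥ 99% of
variance, z_k the percent variance of PC k.

**The regression stage** models mean admixture frequency with Gaussian
Bayesian linear models (flat coefficient prior, inverse-gamma
IG(0.001, 0.001) residual-variance prior, Gibbs chains of 10⁶ iterations,
burn-in 10³, thinning 200), reports pMCMC and ESS per coefficient, and
ranks the 14-model predictor-combination set by DIC. Rank correlations use
tie-corrected Spearman's rho. Geographic distances are haversine
great-circle distances between clade mean coordinates (R = 6378.137 km).

See `docs/methods.md` for the full model description, conventions and
limitations.

## Worked example

```python
import pairflow as pf
from pairflow.association import ModelSpec, fit_bayes_glm, dic, rank_models

table = pf.load_sceloporus_pairs()          # the packaged 21-pair table
res = fit_bayes_glm(table, ModelSpec(("time",), seed=1))
print(res.summary.round(4))
print("DIC", round(dic(res), 2))
```

```
                mean  ci_lower  ci_upper        ess   pmcmc
coef
(Intercept)  22.1127   10.0989   33.8888  4969.1998  0.0004
time         -5.2916   -8.3878   -2.1567  4947.1283  0.0004
DIC 104.37
```

The time coefficient is the change in mean admixture frequency (percentage
points) per million years of divergence: each additional Myr of separation
predicts ~5.3 points less admixture, with a 95% credible interval well
below zero and pMCMC ≪ 0.05 — older pairs exchange fewer genes.

Ranking all 14 predictor combinations:

```python
ranking = rank_models(table, seed=1)
print(ranking.table[["rank", "model", "dic", "delta_dic"]].head(4))
```

```
 rank                                 model     dic  delta_dic
    1         gene_flow ~ time + morphology 103.745      0.000
    2                      gene_flow ~ time 104.267      0.522
    3 gene_flow ~ time + space + morphology 105.553      1.808
    4              gene_flow ~ time + space 106.356      2.611
```

Time plus morphology narrowly beats time alone (ΔDIC < 2: effectively
tied); every top-ranked model contains time, while climate- or space-only
models sit at the bottom.

The same analysis runs end-to-end on synthetic data with known truth:

```python
cfg = pf.SimConfig(n_clusters=2, n_sites=2000, admixture_level=0.05, seed=0)
genotypes, truth = pf.simulate_genotypes(cfg)
q = pf.fit_admixture(genotypes, K=2, seed=1)
```

or from the shell:

```sh
pairflow simulate --seed 0 --out demo/
pairflow filter demo/genotypes.vcf --out demo/filtered.vcf
pairflow fit-admixture demo/filtered.vcf --k 2 --out demo/q.csv
pairflow associate --table sceloporus --seed 1 --out demo/assoc/
```

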