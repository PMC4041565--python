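# irclust

Defining insulin resistance (IR) by clustering, for sibship-structured
cohort data.

Surrogate definitions of IR from fasting measurements are ad hoc, and the
gold-standard measurements (insulin suppression test, euglycemic clamp) are
too invasive for routine use. This package implements an alternative: let
the data define the phenotype. Nine clinical features per person —
triglycerides, total cholesterol, HDL, and oral-glucose-tolerance-test
(OGTT) glucose and insulin at 0/60/120 minutes — are regressed on functions
of age and BMI, and the residuals are clustered by **Gauss-mixture vector
quantization (GMVQ)**: each cluster is a weighted Gaussian component
(prior `p_i`, mean `m_i`, covariance `K_i`) and a point `x` is assigned by
the minimum-distortion / maximum-a-posteriori rule

```
rho_i(x) = -ln p_i + 1/2 (x - m_i)' K_i^{-1} (x - m_i) + 1/2 ln det K_i,
```

fitted with the hard-decision Lloyd algorithm and tree-structured splitting
initialization. The pipeline then

- estimates the number of clusters from bootstrap distortion-decrement
  curves, the gap statistic, and silhouette widths;
- resamples **sibships** (not individuals) in all bootstrap procedures,
  drawing families with probability proportional to sibship size;
- tests clusters for **familiality** with a conditional permutation test
  whose closed-form null expectation for size-`k` families is
  `f_k [1 - C(N-k, n1)/C(N, n1)]`;
- selects cluster-predictive SNPs by **mutual information**
  `I(X;Y) = sum p(x,y) log[p(x,y) / p(x)p(y)]`, after filtering constant and
  under-genotyped SNPs, dropping high-missingness individuals, and imputing
  with per-SNP classification trees; redundant SNPs are collapsed on an
  average-linkage dendrogram of `1 - I/min(H)` distances;
- mines gene-environment interaction candidates from pruned classification
  trees (adjacent splits on a root-to-leaf path suggest a two-factor word)
  and evaluates prediction of cluster membership under asymmetric
  misclassification costs with stratified cross-validation and a
  permutation test on cross-validated AUC.

The study data are restricted, so the package ships a first-class
synthetic-cohort generator with the same statistical structure (287
families / 557 women, published sibship-size composition, cluster shifts on
the published scale, Hardy-Weinberg genotypes with cluster-associated and
near-duplicate SNPs) and known ground truth; every stage is tested against
it.

## Worked example

```sh
irclust --out-dir run --seed 7 simulate
irclust --out-dir run --seed 7 residuals --n-boot 50
irclust --out-dir run --seed 7 cluster --n-boot 5
irclust --out-dir run --seed 7 familiality
```

prints

```
simulated 557 individuals in 287 families
median cumulative variance at 2 components: 0.9884
chosen K: {'decrement': 2, 'gap': 2, 'silhouette': 2}
fit K=2: sizes {1: 178, 2: 379}, 9 iterations, converged=True
 size  n_families  observed  expected
    2         120        62 64.488589
    3          40        26 27.430750
    4          15        13 11.800967
    5           5         3  4.276891
    6           1         1  0.902014
total observed 105, expected 108.90; two-sided p = 0.408 (10000 permutations)
```

Reading: two principal components carry 98.8% of the variability in the 17
age/BMI basis functions; all three model-order criteria agree on two
clusters; the fitted cluster sizes (178/379) match the generator's
configured prevalence; and since the generator assigns cluster labels
independently within families by default, the observed family counts sit on
the random-assignment expectation and the familiality test rightly accepts
the null (p = 0.41). The `snps`, `predict`,
and `report` subcommands continue the pipeline (representative SNPs with
their MI against cluster membership, cost-ratio sensitivity/specificity
tables for the three feature sets, and the two-cluster summary with
fitted values added back).

The same functionality is available as a library:

```python
import irclust as ir

cohort, truth = ir.generate_cohort(seed=7)
residuals = ir.fit_residuals(cohort)
codebook, diagnostics = ir.fit_gmvq(residuals.matrix, k=2, seed=7)
```

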