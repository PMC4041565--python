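# Methods

This note records the model, the choices that were genuinely open when the
package was designed, and what the synthetic tests do and do not establish.

## Residualization

Insulin-resistance phenotyping should not be confounded by age or adiposity,
so the nine clinical features (triglycerides, total cholesterol, HDL, OGTT
glucose and insulin at 0/60/120 min; mg/dl throughout) are residualized on
functions of age (years) and BMI (kg/m²) before clustering.

A 17-function candidate basis (powers up to cubic, square roots, logs, and
sines/cosines at two frequencies of both variables, plus the product
AGE·BMI) is screened by principal components of its correlation matrix,
bootstrapped over sibships. Two reconstruction choices matter:

- **Trig arguments are scaled to a quarter period** over fixed
  physiological ranges (age 20–90 y, BMI 14–45 kg/m²), so every basis
  column is a smooth monotone transform of age or BMI. Applied to raw
  units, sin/cos sweep through many periods across a cohort and become
  noise columns, each carrying its own principal component; with the
  scaling, the first two components carry ≈ 99% of the correlation
  variance and load dominantly on the quadratic terms — the structure the
  screening is meant to exhibit.
- **PCA uses the correlation matrix**, because the raw columns span five
  orders of magnitude (AGE³ vs log BMI).

The production regression is fixed: each feature is fit by OLS on
{1, AGE, BMI, AGE², BMI², AGE·BMI}. `dominant_loadings` is a diagnostic,
not a model selector. Residuals are orthogonal to the design to < 1e-8
relative, and residual + fitted reproduces the data exactly.

## Sibship bootstrap

All resampling draws M individuals uniformly with replacement (M = number
of families) and includes each drawn individual's whole sibship —
equivalently, M sibship draws with probability proportional to sibship
size. This keeps the number of sibships per replicate fixed at M and is
deterministic given (cohort, seed). Note that under size-biased draws the
expected number of *individuals* per replicate is M·Σk²f_k/N (≈ 694 for
the default composition), not N; the procedure is implemented as stated
and this property is simply documented. Repeated families are materialized
as distinct copies with suffixed ids; each replicate row remembers its
source individual, which matters for permutation tests (below).

## GMVQ clustering

Cluster i is a weighted Gaussian (p_i, m_i, K_i); encoding minimizes
ρ_i(x) = −ln p_i + ½(x−m_i)ᵀK_i⁻¹(x−m_i) + ½ ln det K_i, which is the MAP
component choice (the (d/2)ln 2π constant is dropped; it cancels). Numerical
choices:

- Natural logs internally; the length function l(i) = −log₂ p_i is
  reported in bits, and Σ2^(−l) = Σp_i = 1 (admissible with equality).
  A fixed-rate mode (uniform l) exists behind a flag.
- Covariance update uses shrinkage (1−γ)S + γ(tr S/d)I with γ = 10⁻³,
  plus a 10⁻⁸-scale identity floor, to keep components invertible.
  Because the M-step then deviates from exact maximum likelihood by O(γ),
  the distortion sequence is monotone only up to that order; tests allow
  a 10⁻⁴ relative slack.
- Ties in encoding break toward the smallest index. Empty clusters are
  reseeded at the worst-encoded point (counted and logged).
- Convergence: relative distortion change < 10⁻⁸ or 100 iterations.
- Residuals are clustered unstandardized; the component covariances absorb
  scale.
- Initialization is tree-structured (TSVQ): split the component with the
  largest distortion contribution ±ε√λ along its leading covariance
  eigenvector (ε = 0.05), re-running Lloyd after each split; the K = 1..k
  path comes out of one pass.

**Number of clusters.** Three criteria are reported. (1) The decrement
criterion uses the *quantization-error* part of the distortion
(Mahalanobis + ½ log det), averaged over sibship-bootstrap replicates;
chosen K follows the largest decrement. The −ln p_i rate term is excluded
from this curve deliberately: it grows as priors shrink with K (splitting a
single 1-D Gaussian in half raises the full objective by ln 2 − 0.506 > 0),
so only the error part "necessarily decreases" and yields a readable elbow;
the full objective is recorded alongside. (2) The gap statistic is computed
in its standard form — k-means within-cluster dispersion against a uniform
reference in the PCA-aligned bounding box (B = 50 by default) — rather than
from GMVQ assignments, whose Mahalanobis-shaped clusters make the Euclidean
dispersion curve drift; gap and (3) mean silhouette width corroborate the
GMVQ-based criterion, they do not replace it. Cluster label 1 is oriented
to the component with the higher mean fasting-insulin residual.

## Familiality

Conditional on the sibship-size table, N, and the cluster-1 size n1, the
null assigns exactly n1 individuals to cluster 1 uniformly. The expected
number of size-k families represented in cluster 1 is
f_k·[1 − C(N−k,n1)/C(N,n1)] (verified against exhaustive enumeration for
N ≤ 12). The Monte-Carlo test statistic is the total number of families of
size ≥ 2 represented in cluster 1; the p-value is two-sided by the doubling
rule with the add-one correction. Because the statistic is integer-valued,
this p-value is discrete and mildly conservative (measured
P(p ≤ 0.05) ≈ 0.03 under the null); calibration tests check validity and
non-degeneracy at several levels rather than exact uniformity.

## SNP selection

Genotypes are major-allele counts {0,1,2} with missing values. Filters (in
order): SNPs constant across non-missing entries; SNPs genotyped in fewer
than 400 individuals; then individuals with more than 110 missing calls.
Missing entries are imputed by per-SNP depth-5 classification trees trained
on the individuals observed for that SNP, with the other SNPs (mode-filled)
as predictors and a modal fallback; observed entries are never altered.

Pairwise SNP similarity is the mutual information of the 3×3 genotype
table, normalized by the smaller marginal entropy; distance = 1 − NMI.
Default logs are base 2 (bits); base is per-call configurable because the
published worked examples are exact in different bases (the near-duplicate
pair in bits, the near-independent pair in base 10). Average-linkage
agglomeration builds the dendrogram (scipy; its deterministic tie rule
applies).

**Cutting the tree.** Candidate cuts are a fixed grid of redundancy
thresholds, distance 0.1–0.9 (i.e. NMI similarity 0.9 down to 0.1);
identical partitions are scored once by 10-fold cross-validated accuracy of
the baseline classifier at cost ratio 1:1 on the per-node representatives
(each node's representative maximizes MI with cluster membership, ties by
name). A threshold at or above 1 would declare mutually uninformative SNPs
redundant and is excluded. Cutting by *height* rather than by cluster count
is essential here: SNPs truly associated with the phenotype are mutually
dependent *through* the cluster label (pairwise distance ≈ 0.95 in the
default regime, vs ≈ 0.05 for genuine near-duplicates), so any cut into few
clusters would collapse all causal SNPs into one node and keep only one of
them, while a height cut separates them and still merges duplicates.

## Prediction

Interaction mining grows a Gini tree with class weights equalizing
prior × loss ("balanced"), pruned by cost-complexity with 10-fold CV on
balanced accuracy: candidate strengths are midpoints of the pruning-path
intervals (plus one past the root), the tree is kept only if its best
candidate beats the root by more than 3 standard errors (so pure noise
collapses to the root), and the 1-SE rule then picks the strongest pruning.
Every split variable on a root-to-leaf path is a main-effect word; adjacent
distinct variables form two-factor words; self-pairs and higher orders are
ignored; sub-word closure holds by construction.

Feature sets: FS1 = {AGE, BMI, AGE², BMI², AGE·BMI}; FS2 = FS1 +
representative SNPs (0/1/2); FS3 = FS2 + one product column per mined pair
(standardized constituents; SNP constituents centered only). The default
classifier is a linear SVM in a scaling pipeline with class weights
proportional to the misclassification costs (FN on the insulin-resistant
class costs `ratio`, FP costs 1); any scikit-learn classifier can be
substituted — the evaluation protocol is the point. The CV harness
aggregates sensitivity, specificity, overall accuracy, and
miscost = ratio·FN + FP over stratified held-out folds, for ratios 1.8–2.3
by default; a builder callback lets selection and mining re-run inside each
training fold (verified leakage-free by a canary test that injects a
feature equal to the held-out labels after the split). The added value of
the SNP block is tested by permuting SNP rows across individuals,
recomputing interaction products from the permuted SNPs, and comparing
cross-validated AUCs with an add-one one-sided p-value.

## Cluster comparison

Summaries add fitted values back so means/sds are on the measurement scale.
Welch t uses n−1 sds (this convention reproduces the published t values to
2 decimals on the printed summaries; the published triglycerides row is
internally inconsistent — its t implies a cluster-1 mean of 155.66, not the
printed 55.66 — and the consistent value is used everywhere). The
permutation pooled-t suite runs over sibship-bootstrap replicates; each
permutation re-divides the *source* subjects into groups of the observed
cluster sizes and propagates the division through each row's source
individual. Permuting replicate rows directly would ignore that bootstrap
copies of one person are tied: measured type-I error 0.22 at α = 0.05,
versus 0.054 for the source-level permutation. Wilcoxon rank-sum p-values
are computed per replicate alongside; per-feature rejection fractions at
α = 0.05 are reported. No multiplicity correction is applied across the 11
features.

## Synthetic cohort: what it does and does not emulate

Defaults reproduce the study conditions: sibship composition
{1: 106, 2: 120, 3: 40, 4: 15, 5: 5, 6: 1} (287 families, 557 women);
age ~ N(49.5, 8.5²) truncated to [30, 75]; BMI ~ N(24.7, 3.5²) truncated to
[16, 40]; cluster-1 prevalence 177/557 with zero within-family correlation
(a free parameter, since the real clusters showed no familiality); feature
means = intercept + moderate age/BMI dependence (each design term sized at
0.10–0.35 of the feature's residual sd per term-sd; HDL decreasing);
cluster-mean shifts equal to the published cluster differences
(triglycerides via the t-consistent value); homoscedastic residual sds
equal to the published cluster-2 sds. Genotypes: 100 SNPs — 3 associated
(major-allele frequency 0.75–0.90 in cluster 2, shifted down 0.25 in
cluster 1), 3 near-duplicate copies (flip probability 0.01, one copying an
associated SNP), 2 constant, 2 under-genotyped (35% missing), the rest
Hardy-Weinberg at frequencies U(0.5, 0.95); 2% base missingness plus an
elevated-missingness 2% of individuals.

Not emulated: within-cluster feature correlations beyond those induced by
age/BMI, heteroscedastic clusters (the real cluster 1 is wider),
linkage-disequilibrium blocks beyond explicit duplicates, genotyping error
beyond uniform flips, males, parents, or SSPG. Passing tests therefore show
the algorithms are correct and well calibrated under the stated structure,
not that real-data effect sizes or the published prediction tables
(which depend on the restricted genotypes) are reproduced. Clinical values
are clipped at zero to respect their domain; at the default sds this
affects < 3% of draws of the smallest-scale feature.

## Problem sizes in tests

The test suite runs the study-scale cohort (n = 557) throughout, with
Monte-Carlo replicate counts chosen per check: 20 seeded runs for
model-order selection (bootstrap 5, gap references 20 per run), 50
replicates for SNP-recovery power, 300/80/6-cohort batches for the three
null-calibration checks, and 10,000 permutations/draws where a single run
is compared against a closed form. These sizes put Monte-Carlo error well
inside each test's assertion band.
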