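# Methods

## The fingerprint dissimilarity

The central statistic is the weighted Manhattan dissimilarity between two
samples' metabolite profiles,

    D_ij = (1/K*) Σ_k |Y_ki − Y_kj| / √(Y_ki² + Y_kj²),

with Y_ki ≥ 0 the relative abundance of metabolite k in sample i. The
denominator √(Y_ki² + Y_kj²) estimates the standard deviation of the
abundance difference, which standardizes every feature's term into
[0, 1]: a trace alkaloid and a dominant surface lipid contribute on the
same footing. The sum runs over the K* features that are positive in at
least one of the two samples.

Normalization by K* (rather than the total feature count K) is what
pins the statistic to its stated range: profiles with completely disjoint
constituents score exactly 1.0, because every informative term is 1 and
features absent from both samples — which say nothing about the pair's
difference — are not allowed to dilute the average. A strict mode
(`normalization="all"`) dividing by the full pairwise-complete feature
count is provided for comparison; it is bounded by the fraction of
features informative for the pair and cannot reach 1 when shared
absences exist.

Properties (all property-tested):

* 0 ≤ D ≤ 1 for any non-negative profiles; D = 0 iff identical; D = 1
  iff constituent-disjoint.
* D(c·y_i, c·y_j) = D(y_i, y_j) for any common factor c > 0. This
  invariance does **not** extend to rescaling a single sample — a
  per-sample normalization step upstream changes D, and the simulator's
  per-sample scale factors exist precisely to exercise that distinction.
* D is symmetric but is not guaranteed to satisfy the triangle
  inequality, and distance matrices built from it are generally
  non-Euclidean (classical MDS reports negative eigenvalues).

Numerical notes: per-feature terms use `hypot` for the denominator, so
subnormal and very large abundances do not under/overflow; a pair with no
informative feature (both profiles all-zero) has an undefined distance —
the scalar function raises, while the matrix builder records NaN and
warns, so one pathological pair does not void a whole matrix. Missing
(not-measured) entries are removed pairwise *before* support is
determined; a missing value never counts as a zero.

## Zero vs missing

Mixed designs measure different platform blocks on different samples, so
the data model distinguishes `0` (the platform measured the feature and
detected nothing — informative) from an empty cell (the feature was not
measured — uninformative). Zeros participate in ranking, distances and
ratios; missing values are deleted pairwise everywhere. This convention
is this package's choice; upstream resources rarely state one.

## Replicate QC

Agreement between replicates is scored by Spearman rank correlation with
average ranks for ties (scipy's implementation) and pairwise-complete
deletion, computed for every replicate pair within an accession × organ ×
stage cell. Rank correlation is invariant to any strictly increasing
transform of either profile, so instrument response drift between runs
does not depress the score. A replicate is flagged when its *median*
correlation to co-replicates falls below a threshold (default 0.7 — a
screening default, not a published value; the median makes the flag
robust to one bad partner). Groups with a single replicate are skipped
and reported.

## Differential abundance

Two-group contrasts use Welch's unequal-variance t statistic with
Welch–Satterthwaite degrees of freedom and a two-sided p-value. Welch is
the safer default for small MS replicate groups whose variances rarely
match. Convention: two constant groups with equal value give t = 0,
p = 1; constant-but-unequal groups are degenerate (the scalar function
raises; the volcano driver records NaN for such features rather than
fabricating an infinite statistic). At n = 5 vs 5 the test is slightly
conservative — the observed null rejection fraction at α = 0.05 on the
log-normal generator is ≈ 0.04, inside the calibration band the tests
assert.

The volcano x-axis is log₂((mean_A + c)/(mean_B + c)) with pseudocount
c = half the smallest positive value in the dataset (configurable,
including c = 0). A data-scaled pseudocount keeps ratios finite when a
feature drops out of one group while preserving the statistic's scale
equivariance; both the raw ratio and its log₂ are exported. Raw
p-values are the primary y-axis; Benjamini–Hochberg q-values
(statsmodels) are an opt-in column.

Ratio panels (one panel per accession, one organ contrast) and all-pairs
accession fingerprints (organs pooled, every ordered accession pair)
share a single explicit feature ordering — platform block, then chemical
class, then mean log-ratio across panels, then feature id — emitted with
the tables so panels are directly comparable and reproducible. Within
one call every ratio uses the same pseudocount, which makes fingerprint
profiles exactly antisymmetric: log-ratio(a, b) = −log-ratio(b, a).

## Ordination and clustering

MDS is classical Torgerson scaling: double-center −½D², eigendecompose,
keep the leading axes with positive eigenvalues. It is deterministic,
exact on genuinely Euclidean 2-D distances (Procrustes RMSE < 1e-6 in
tests), and reports the negative eigenvalues produced by non-Euclidean
input rather than hiding them. Classical scaling optimizes the strain of
the Gram matrix, not raw stress; on distance matrices with real
low-dimensional structure it also dominates random configurations on
stress (tested), but on near-equidistant unstructured distances its
shrunken coordinates need not — no stress-majorization refinement is
applied by default.

Clustering operates on max-standardized abundances: each feature divided
by its maximum over the selected samples, mapping every feature into
[0, 1] with its maximum at 1 (idempotent; all-zero features are dropped
with a warning). K-means uses seeded k-means++ with n_init restarts
(scikit-learn); hierarchical clustering uses scipy's agglomerative
linkage (average by default — a middle ground between single-linkage
chaining and complete-linkage compactness; no linkage is canonical for
this analysis) on Euclidean distances of the standardized columns, or on
a precomputed distance matrix. k is always user-supplied; the package
does not select it. Partition agreement is measured by the adjusted Rand
index (scikit-learn), which is label-permutation invariant.

## The synthetic-data generator

The generator emulates the fingerprinting study the analysis was built
for: 5 accessions in 3 groups (three North American accessions that
resemble one another, one North American outlier, one Eastern European
accession), 5 aerial organs, 5 replicates per accession × organ (25
samples per organ), and platform blocks of 21 + 119 + 83 + 222 = 445
features. Abundances follow a log-normal model with additive log-scale
effects:

    Y[k, j] = s_j · exp(μ_k + α_{g(a),k} + β_{o,k} + ε) · present

| parameter | default | meaning |
|---|---|---|
| baseline_log_mean / sd | 8.0 / 1.5 | feature baselines span ~e⁵–e¹¹, the dynamic range of MS peak areas |
| group_effect_sd | 1.0 | accession-group effects, ~e±1 fold changes |
| organ_effect_sd | 1.0 | organ effects, same scale |
| replicate_cv | 0.25 | log-scale technical noise, ~25 % CV |
| dropout_prob | 0.1 | constituent absence per group × organ cell |
| scale_factor_range | (0.8, 1.25) | per-sample multiplicative factors |

Log-normality with additive log effects is the standard working model
for MS intensities; no generative model is published for this design, so
these magnitudes were fixed once as field-typical values. Dropout is
drawn per accession-group × organ cell, not per replicate: absence of a
constituent is a property of the material, which both makes D = 1
reachable by construction and gives groups qualitative (presence) as
well as quantitative signatures. Per-sample scale factors are on by
default so that analyses claiming scale invariance are exercised against
data that actually varies in scale. All draws come from one
`numpy.random.Generator` seeded explicitly; a seed fully determines the
dataset byte-for-byte.

Two auxiliary generators support calibration: a null two-group dataset
(both groups from the identical log-normal; every feature truly null)
and a spiked variant multiplying a deterministic feature subset by a
known fold in one group.

What the generator does **not** emulate: correlated features (pathway
co-regulation), missing-at-random platform gaps, retention-time drift,
batch effects, heavy-tailed contamination, or intensity-dependent
variance. Passing recovery tests therefore demonstrates correctness of
the computations under the stated model, not robustness of the study
design to real-data pathologies.

## Test and acceptance problem sizes

Stochastic checks run at sizes chosen to keep the full suite fast while
leaving clear statistical margins: 10,000 random pairs for the distance
bounds; 20 random 10 × 50 datasets for the vectorized-vs-naive oracle
(tolerance 1e-12); 100 seeded simulations (445 features × 25 samples)
for clustering recovery, requiring exact recovery (ARI = 1) in ≥ 95 of
them at group separation 5× the replicate noise; 1,000 null features at
5 vs 5 replicates for the type-I band 0.05 ± 0.014 (two binomial
standard deviations); and 600-feature spiked datasets for power
monotonicity across folds 1.5 / 2 / 4. `scripts/acceptance.py` recomputes
the same quantities end-to-end from a single `--seed`.

## Known limitations

* D_ij is a dissimilarity, not a metric; downstream consumers that
  assume the triangle inequality (some tree methods) should not be fed
  these matrices blindly.
* The volcano applies one pseudocount to the whole dataset; platforms
  with very different abundance floors may warrant per-platform
  pseudocounts.
* `standardize_max` is sensitive to a single outlier replicate (it sets
  the feature's maximum); run QC first.
* Hierarchical and K-means results are reported for user-chosen k only;
  no gap statistic or silhouette selection is included.
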