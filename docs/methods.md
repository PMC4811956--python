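# Methods

This note records the models, conventions and numerical choices behind
`radhist`, and what the synthetic experiments do and do not establish.

## Feature extraction

**Discretization.** All texture features discretize intensities inside the
mask into `n_bins` equal-width bins between the masked minimum and maximum
(default 32, configurable).  Min-max binning makes every texture feature
invariant to adding a constant to the image; the bin count is a
conventional radiomics default rather than a value dictated by theory, so
it is exposed in `ExtractionConfig`.

**First-order statistics (15).** The fourteen classic descriptive
statistics plus total energy (energy × physical voxel volume).  Variance,
standard deviation, skewness and kurtosis use the population (divide-by-n)
convention; kurtosis is the raw moment ratio m4/m2² (≈3 for a Gaussian),
and both moment ratios are defined as 0 for constant input.  Entropy and
uniformity use the same equal-width histogram as the texture features.

**Shape (8).** Volume is voxel counting × voxel volume.  Surface area is
exact voxel-face counting: every exposed face contributes its physical
area.  This is exact for axis-aligned shapes and oracle-checkable, at the
cost of overestimating curved surfaces (a staircase sphere carries ~1.5×
the smooth sphere's area), so under this convention the axis-aligned cube
is the most "spherical" attainable mask.  Sphericity, compactness 1/2 and
spherical disproportion are the standard functions of (V, A); the maximal
3D diameter is the largest Euclidean distance between surface-voxel
centers.

**GLCM (22) and GLRLM (11).** Co-occurrences are counted over the 13
unique 3D direction vectors at voxel distance 1 (spacing-agnostic lattice
offsets), symmetrized and normalized per direction; runs are maximal
same-level sequences along each direction, broken by mask boundaries.
Features are computed per direction and averaged, which makes the averaged
values exactly invariant under 90° rotations (the direction set is closed
under axis permutations and sign flips — a tested property).  Feature
formulas follow the classic co-occurrence/run-length definitions with
gray-level indices 1..Ng, log base 2, and 0·log 0 = 0; correlation and
information-measure features are defined as 0 when their denominators
vanish.  Run percentage divides the per-direction run count by the number
of masked voxels.

**Wavelet subbands.** A single-level undecimated (stationary) separable
transform with coiflet-1 filters and symmetric (half-sample mirror)
boundary extension, implemented as centered cross-correlation with the
PyWavelets decomposition filters along each axis.  Undecimated filtering
preserves the grid, so the tumor mask applies unchanged to every subband;
a decimated transform would break that alignment.  Subband labels order
the per-axis filters as (axis0, axis1, axis2), e.g. HLL = high-pass on
axis 0.  The intensity and texture blocks (15 + 22 + 11 = 48) are
recomputed on each of the 8 subbands: 56 + 8 × 48 = 440 features in total.

## Stage-1 selection: correlation elimination

The Pearson correlation matrix and every feature's mean absolute
off-diagonal correlation C are computed once.  Offending pairs
(|r| > M, default M = 0.8) are visited in descending |r| (ties by
lexicographic name pair); if both members are still alive the one with the
larger C is dropped (ties: the lexicographically later name).  Because
every offending pair loses at least one member, the survivor set can
contain no pair above M — asserted on every run.  Zero-variance features
are removed first (their correlation is undefined); the label column never
enters the computation.  The procedure is deterministic and idempotent.
Visiting pairs in a fixed global order with frozen C resolves the order
ambiguity inherent in "remove the member with higher average correlation"
descriptions; recomputing C after each removal is a different (also
defensible) convention and would retain slightly different sets.

## Stage-2 selection: the 24 ranking methods

Impurity-family scores operate on a class × attribute-value contingency
table built from equal-frequency discretization (default 4 bins, quantile
edges).  All gains use expected (probability-weighted) posterior
impurities; "Equal" variants weight every value column by 1/|a| instead of
p(a_j) and coincide with their weighted counterparts whenever the column
counts are equal (a tested identity).  MDL is the description-length gain
computed via log-gamma; Accuracy is the gain in majority-class prediction
accuracy.  The Hellinger and Euclidean scores measure how far the
within-column class distribution moves away from uniform,
score = Σ_j w_j·P(p(·|j)) − P(p(·)) with P_hell(p) = 1 − Σ_i √(p_i/c) and
P_euclid(p) = ‖p − u‖₂.  These distances *grow* with class purity, so the
gain is oriented posterior-minus-prior — the same sign pattern as the
Σp² purity form of the Gini gain — making every registered score
"higher is better".

The Relief family min-max normalizes features (per-attribute differences
in [0, 1]) and uses the normalized Manhattan distance.  For each reference
instance (all instances in order, by default) the k nearest same-class
hits and, per other class, k nearest misses are found with deterministic
index tie-breaking; attribute weights decrease with hit differences and
increase with miss differences, the latter scaled by p(class)/(1 −
p(class(R))).  Variants: equal 1/k weights (ReliefFequalK), Gaussian rank
weights exp(−(rank/σ)²) (ReliefFexpRank, σ = 20), the best prefix mean
over k' ≤ k (ReliefFbestK), inverse-distance and inverse-squared-distance
weights (ReliefFdistance / ReliefFsqrDistance), per-pair
difference-over-distance (ReliefFmerit), equal or exponential class-prior
weighting (ReliefFavgC / ReliefFexpC), a pooled other-class neighbor set
with per-neighbor prior ratios (ReliefFpe), seeded resampled references
(ReliefFsmp), and classic two-class Relief (k = 1, no prior weighting).
For *binary* labels the prior miss weight is identically 1, so equalK,
avgC, expC and pe coincide on two-class data; they differ once three or
more classes are present.  MDLsmp scores MDL on a seeded stratified
half-subsample.  Defaults k = 10, m = all instances, σ = 20 are common
Relief practice, fixed for reproducibility.  A class with fewer than k
members contributes all it has.  Ranking ties break lexicographically, so
every ranking is deterministic.

## Classifiers

All three emit the positive-class (adenocarcinoma) probability.  Gaussian
naive Bayes models each feature with class-conditional normals (posterior
in log space; per-class sd floored at 1e-9 so constant features stay
finite); features are continuous after standardization, which makes the
Gaussian likelihood the natural density model.  The random forest uses 100
bootstrap trees, √p candidate features per split, Gini criterion, grown to
purity; with pure leaves the averaged tree probability equals the fraction
of trees voting positive.  An optional locally-weighted voting mode
(weights = each tree's accuracy on the 30 training instances nearest the
query) is provided but OFF by default — it reflects an
implementation-specific mechanism whose exact definition is not
standardized.  KNN uses k = 9 with Euclidean distance; the score is the
positive fraction among the neighbors.  Naive Bayes and KNN standardize
features by training-cohort mean/sd inside their pipelines, so validation
cohorts are transformed leakage-free.  Models serialize to a versioned
JSON container (forest trees as nested node records).

## Evaluation

AUC is the tie-aware Mann–Whitney statistic.  Permutation p-values are
one-sided with the add-one correction p = (1 + #{AUC_perm ≥ AUC_obs}) /
(B + 1), strictly positive and type-I valid.  The univariate screen is
orientation-free (reports max(auc, 1 − auc) with a direction flag and
permutes the same oriented statistic) because features may run higher in
either subgroup; it shares one set of B label permutations across
features, which keeps the screen O(np + pB) without biasing per-feature
p-values.  Multiplicity is controlled by Benjamini–Hochberg at 5% FDR.
Confidence intervals use the Hanley–McNeil normal approximation (DeLong
available as an option).  The decision cutoff maximizes Youden's J on the
training ROC (ties → lowest cutoff) and is then applied unchanged to the
validation scores.

Note a granularity consequence of B = 1000 permutations: the smallest
attainable p is 1/1001, so on a 440-feature table BH can declare
significance at rank 5 only if p ≤ 0.05·5/440 ≈ 0.00057 < 1/1001 — with
exactly 5 planted informative features the full-table screen necessarily
reports 0 discoveries.  On the 67-feature post-filter table the rank-5
threshold (0.0037) clears the floor and all 5 planted features are
flagged.  Large discovery counts require either many truly associated
features or more permutations.

## Benchmark grid

For each of the 24 methods the training cohort is ranked once; for each
size in 5, 10, …, 45 the top features are kept; each classifier is fit on
training data and scored on validation by AUC — 648 cells.  Rankings,
standardization and cutoffs use training data only (a shuffle test
verifies validation labels cannot leak into the training-side decisions).
Per-cell seeds derive from the run seed via `SeedSequence`, so the grid is
reproducible cell-for-cell.  The summary reports, per classifier, the
median ± SD over all method × size cells (per-size medians are recorded
separately for inspection), the best and worst methods by their maximal
cell, and the size of the best cell.

## Synthetic data

Feature tables come from a block latent-factor model: members of a block
share one standard-normal factor z with x = √r·z + √(1−r)·ε, giving exact
expected within-block correlation r (default 0.95) and unit variance.
Labels are Bernoulli draws (train 0.75/0.25 positive, validation
0.41/0.59, mirroring a two-institution cohort pair with distribution
shift); informative features carry a class-conditional mean shift of
d = 1.2 standard deviations.  Informative features are placed among the
*independent* features rather than inside correlated blocks: under the
elimination rule above, the survivor of a block knockout is essentially
the member with the smallest noisy column mean, so a designated block
member would survive filtering only ~60% of the time at n = 200 —
independent placement makes survival deterministic and keeps recovery
experiments well-posed.  The paper-like preset uses 40 blocks (27 of size
10, 13 of size 11) plus 27 independent features — 440 features reducing to
exactly 67 at M = 0.8 — with 5 informative; uniform block sizes cannot
reach 67 survivors because 440 − 67 = 373 is prime, hence the mixed sizes.

Image cohorts are centered ellipsoids (radii uniform in a configured
range) filled with Gaussian noise at a class-dependent mean/sd, optionally
smoothed with a Gaussian kernel (the smoothed field is rescaled so its sd
matches the parameter), over a noisy lung-like background near −800 HU.
A `p_positive` parameter (default 0.5) sets the label law.

What the generators do **not** emulate: CT acquisition physics, scanner
and reconstruction variability, delineation uncertainty, realistic
anatomy, or the empirical correlation spectrum of real radiomic features
(real cohorts show far denser redundancy — the mean absolute pairwise
correlation of the synthetic preset is ~0.07, concentrated inside blocks).
Passing tests therefore establish the *correctness and internal
calibration* of the pipeline (oracle equivalence, FDR/permutation
calibration, leakage-freedom, recovery of planted signal), not clinical
performance; published cohort-level numbers depend on data this package
does not ship and are out of its scope.

## Numerical conventions and degenerate inputs

Log base 2 throughout; 0·log 0 = 0.  Constant features: texture levels
collapse to one bin (entropy 0, uniformity 1); Relief weights exactly 0;
correlation undefined → removed before elimination; naive Bayes sd floored
at 1e-9.  Single-voxel masks are rejected for texture (co-occurrence
undefined).  Contingency tables with a single class or a single value
column score 0 rather than erroring.  Selection sizes above the available
feature count are capped and flagged.  All tie-breaks (ranking scores,
neighbor distances, cutoff candidates, elimination pairs) are
deterministic, so identical seeds give byte-identical outputs.

## Problem sizes used in the test and acceptance runs

Oracle comparisons run on 20 random ≤5³ volumes (texture), 50 random
n ≤ 20 datasets (Relief), and 100 random n ≤ 30 score vectors (AUC).
Calibration uses 200 null features at n = 100 with 1000 permutations.
Recovery and the full 648-cell grid run on the paper-like preset
(200/150 samples, 440 → 67 features) over 10 seeds, sizes chosen so the
complete suite and the acceptance script each finish in well under a
minute of compute per stage on a single CPU.
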