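# Methods

## Model and procedure

`mapeval` treats replicate agreement and annotation agreement in
perturbation-profiling data as retrieval problems. A *profile* is a row of
a numeric feature matrix with attached categorical metadata. A retrieval
task is fully specified by a block design: lists of metadata columns on
which a candidate must agree (`sameby`) or disagree (`diffby`) with the
query to count as a correct (positive) or incorrect (negative) match.
Candidates satisfying neither predicate are simply absent from the rank
list — they are not forced into the negatives — because each task is a
comparison between one query group and one reference group, not a
classification of the whole dataset. Metadata comparison is exact,
case-sensitive equality; a missing (NaN) value never matches and never
counts as "different", so unannotated rows drop out of both roles rather
than silently grouping together.

For each query, candidates are sorted by increasing distance (cosine by
default; Euclidean and Pearson-correlation distance are options) and the
sorted list is binarized. Average precision is the conventional
non-interpolated form: the mean of precision@k over the ranks k that hold
a positive, which equals the recall-increment sum Σ_k (R_k − R_{k−1}) P_k
with R_0 = 0 and normalizer n_pos (the number of positives, M−1 for a
group of M replicates). The group score mAP is the arithmetic mean of its
members' APs. Ties in distance are broken pessimistically — negatives
ahead of positives — so tied candidates can only lower a score, never
manufacture significance; a seeded random tie mode exists for sensitivity
checks. Distances are computed exactly in double precision; AP depends
only on the ordering, so any monotone transform of the distance leaves
scores unchanged (property-tested).

## Permutation null and p-values

Under the null hypothesis that query and reference profiles are
exchangeable, every arrangement of the binary rank list is equally
likely, so the null AP distribution depends only on (n_pos, n_total) and
has exactly C(n_total, n_pos) support points. Configurations with at most
10,000 arrangements (configurable) are enumerated exhaustively; larger
ones are approximated with 10,000 uniformly random lists (configurable,
seeded). Shuffling the rank list is equivalent to shuffling the profile
labels and never requires recomputing distances, which is what makes the
null cacheable by its two parameters; the cache can be persisted to a
columnar CSV.

The p-value is the fraction of the null at or above the observed score.
By default the estimate is +1-smoothed — (1 + #{null ≥ obs}) / (1 + n) —
the standard permutation convention that keeps p strictly positive; a
`raw` mode returns the literal unsmoothed fraction and is what the
simulation benchmark thresholds. Note the inclusive inequality: an
observed AP of 1.0 is compared against the null mass *at* 1.0. One
consequence at very small designs: with 2 replicates and 12 controls the
best achievable raw p is P(AP = 1) = 1/13 ≈ 0.077, so no score can clear
α = 0.05 — small designs are structurally unable to reach significance,
and the benchmark shows zero recall there rather than an artifact of a
strict-inequality shortcut.

For a group of M queries, the null mAP draw k is the mean over members of
draw k of each member's null AP sample vector, with members that share a
(n_pos, n_total) configuration reusing the *same* vector ("coupled" mode,
the default): one joint reshuffle outcome drives the whole group. Mixed
configurations (consistency groups of unequal size) average elementwise
across their per-configuration vectors. An "independent" mode that
resamples each member separately is provided for comparison. The choice
matters: member APs within a real group are positively correlated (they
rank the same candidates, and an outlier replicate lowers every member's
AP at once), and no null built from rank lists alone can represent that
correlation. The coupled null over-disperses the null mAP and is
conservative — measured on null-identical simulated data the
false-positive rate at raw p < 0.05 is ≈ 0.8% at 4 replicates / 36
controls — while the independent null under-disperses it and roughly
doubles the nominal rate (≈ 10% measured). The coupled default was chosen
because it never overstates evidence and reproduces the benchmark
behavior expected of the retrieval test; per-query AP p-values (single
member, no averaging) are exactly calibrated either way. Exact
calibration of the group test would require permuting profile labels and
recomputing distances, which the framework deliberately avoids.

When several groups are scored together, Benjamini–Hochberg correction
(via `statsmodels.stats.multitest`) produces q-values, and *percent
retrieved* is the percentage of groups with q < 0.05. The simulation
benchmark instead thresholds raw, unadjusted p-values at 0.05, because
its recall is a per-condition power estimate, not a discovery set.

## Tasks

- **Phenotypic activity**: each replicate of a perturbation queries its
  M−1 siblings against the N negative controls. Optional extra
  sameby/diffby constraints express restricted designs (same well
  position across plates, same plate different wells, ...).
  Perturbations with one replicate are skipped with a logged reason.
- **Consensus**: per-perturbation feature-wise median over replicates;
  metadata constant within every group is retained, varying columns are
  dropped. Median aggregation is idempotent and bounded by the member
  range (property-tested).
- **Phenotypic consistency**: on consensus profiles, same-label members
  are retrieved against all differently labeled profiles. An *activity
  gate* (the set of perturbations that passed the activity threshold)
  should be applied first so that mutual inactivity is not mistaken for
  biological similarity.
- **Phenotypic distinctiveness**: like activity, but the references are
  all other perturbations' replicates and controls are excluded.
- **Multi-label extension**: when perturbations carry several
  annotations, AP is computed per (perturbation, label) pair — positives
  are the other perturbations with that label, negatives all remaining
  profiles regardless of their other labels (an option drops candidates
  that share a different label with the query). The result is a sparse
  P×T matrix aggregable by row (per-perturbation) or column (per-label
  mAP, whose significance uses the group null above). The AP normalizer
  is the positive count excluding the query, consistent with the
  single-label definition, so single-label data reduces exactly to the
  consistency task (tested).

## Comparator baselines

- **mp-value**: the pooled two-group sample is projected onto its
  principal components, each component's scores are weighted by its
  fraction of explained variance, and the Mahalanobis distance between
  group centroids is computed with the pooled covariance of the weighted
  scores plus a small ridge (10⁻⁶ · trace/k) for invertibility.
  Significance is by group-label permutation (default 1,000). The PCA is
  computed once: permuting labels leaves the pooled sample unchanged, so
  re-fitting PCA inside each permutation would reproduce the same
  projection (up to component sign, which Mahalanobis ignores).
- **MMD**: the unbiased MMD² estimator with an RBF kernel
  exp(−d²/(2σ²)), σ set to the median pairwise Euclidean distance of the
  pooled sample. The kernel matrix is permutation-invariant, so label
  permutations only re-index block sums. All points identical (zero
  median distance) is an error, surfaced to the benchmark as a failure.
- **k-means separation**: 2-means on the pooled sample, random centroid
  initialization, best of 10 restarts by inertia (scikit-learn). Success
  requires the cluster partition to equal the group partition exactly;
  a `purity` field reports the softer agreement fraction.

## Synthetic data generator

`simulate_condition` emulates the simplest caricature of a profiling
screen: control profiles draw every feature i.i.d. from N(0, 1) (or
standard Cauchy for heavy-tail stress tests), and each perturbation's
replicates draw a fixed fraction of features from N(1, 1) — a one-sigma
mean shift — with the rest from the control distribution. Grid values
follow the benchmark design: 100 perturbations per condition, 2–4
replicates, 12/24/36 controls, 100–5000 features, perturbed fractions
0.01–0.64 on a binary-exponential scale; `frac_perturbed = 0` is the
explicit null condition for type-I measurement, while a positive fraction
that rounds to zero perturbed features is rejected as a configuration
error. The perturbed features are the first ⌈f·d⌉ indices — AP and all
three baselines are invariant to feature permutation, so randomizing the
subset would only add bookkeeping (the invariance is itself tested).

What the generator deliberately lacks: feature correlations, plate/batch
structure, well-position effects, heteroscedastic features, outlier
replicates, and any relationship between features. Passing benchmarks on
this generator therefore demonstrates the statistical machinery (ranking,
nulls, calibration, relative power under sparse mean shifts), not
robustness to the technical variation of real screens — that is what the
block-design constraints and per-plate normalization are for on real
data.

## Problem sizes and reproducibility

The shipped benchmark and test suite run at desk scale: the reduced grid
(features {100, 1000} crossed with either the full fraction range at 4
replicates / 36 controls, or all replicate/control counts at the 1%
fraction), 100 perturbations per condition, 2,000 permutation draws, and
three seeds — about two minutes of single-CPU time in total, with every
random stream derived from explicit seeds (`SeedSequence` spawning, so
condition, method and perturbation streams are independent). The full
6×7×3×3 grid of the complete study is exposed through the same API and
scales linearly.

## Normalization and feature selection

Standardization subtracts the feature mean and divides by the population
(ddof = 0) standard deviation, globally or per plate; features constant
within a block are dropped with a warning. MAD-robustize uses the
per-plate median and median absolute deviation with the normal-consistency
constant c = 1.4826 (so MAD·c estimates σ under normality and the two
schemes are comparable); features with zero MAD on any plate carry no
within-plate signal and are dropped by default, or kept with a
denominator of c·MAD + ε when an explicit ε is supplied. Feature selection
drops, in order: blocklisted names (user-supplied fnmatch patterns — no
blocklist ships with the package), features with missing values,
variance below the floor, the later member of each feature pair with
|r| above the correlation ceiling (deterministic keep-first rule), and
features with any |value| beyond the outlier bound; a report of dropped
features and reasons accompanies the reduced table.

## Known limitations

- Group-level (mAP) p-values are conservative by construction (coupled
  null); raw per-group power at small effect sizes is correspondingly
  lower than a fully recomputed label-permutation test would give, and
  two-sample baselines can out-power the retrieval test when only a few
  features carry signal.
- Significance is discrete: tiny designs (e.g. 1 positive among ≤ 19
  candidates) cannot reach p < 0.05 at all.
- Mahalanobis distance is not offered as a profile metric (it would need
  a covariance estimate the framework does not define); cosine, Euclidean
  and Pearson are.
- No batch correction is included: profiles are assumed normalized and
  batch-corrected upstream, with the block-design constraints available
  to *measure* residual plate and well effects rather than remove them.
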