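# Methods

## Models

### Lernmatrix

Binary heteroassociative memory. Learning starts from the zero matrix
**M** ∈ ℝ^{m×n} and, per association (x, k) with x ∈ {0,1}ⁿ, applies the
three-case Steinbuch rule to row k: +ε where x_j = 1, −ε where x_j = 0,
rows of other classes unchanged. ε is any positive constant; we default to
ε = 1 and expose it as a parameter. Because recall compares row scores
Σ_j m_ij x_j, whose ordering is invariant to a positive common factor,
predictions do not depend on ε (tested). Recall returns the *set* of
maximal rows as a binary class vector; the classifier wrapper collapses it
to the smallest flagged index. The memory accepts only strictly binary
inputs — real inputs are rejected with a diagnostic naming the offending
component, never implicitly thresholded.

### Linear Associator

**M** = Σ_μ y^μ (x^μ)ᵀ, recall y = **M** x with no thresholding. For
mutually orthonormal inputs the cross terms vanish and recall of a stored
input reproduces its stored output; we verify this to 1e−10 absolute error
on a random 16-dimensional orthonormal basis.

### CHA / CHAT

Linear-Associator learning with class one-hot outputs of size m, followed
by Lernmatrix-style arg-max recall. Row k of the learned matrix is the sum
of training patterns of class k; the class score of a query is the inner
product of that row with the query. CHAT first moves the origin to the
training centroid, which makes predictions invariant to any common
translation of the data (the centroid absorbs it) and to positive scaling
(scores scale by a²). CHA is the translate_axes=False special case.

### CHAT-OHM

Outputs are coded per *pattern* (size p, Kronecker delta at μ), so the
learned matrix is the stack of translated training patterns — an identity
we assert at fit time against explicit outer-product accumulation on sets
up to 200 patterns (the accumulation is O(p²n), so larger sets rely on the
assertion's inductive reach rather than paying the cost every fit).
Classification is by majority voting over the recovered vector:

* recovered vector ỹ_i = 1 iff score u_i is within tolerance of max(u);
* counting vector t^k = ỹ ∧ c^k with c^k the class-k masking vector;
* predicted class = arg-max_k Σ t^k.

With a unique maximal score this reduces to 1-NN under the centered
inner-product similarity, which is the basis of the oracle test (100%
agreement required whenever the maximum is unique). The voting path is
exercised by exactly symmetric fixtures where all scores tie.

## Numerical choices

* **Score ties.** A score belongs to the arg-max set iff
  max(u) − u_i ≤ 1e−9 · max(1, |max(u)|). Exact equality on floats would
  make the symmetric tie fixtures fragile; a relative-only tolerance would
  misbehave near max(u) = 0, hence the sign-aware max(1, ·) floor.
  Lernmatrix scores are integer multiples of ε, so its recall uses exact
  equality.
* **Tie rules.** Tied class scores or tied vote counts resolve to the
  smallest class index; tied distances at the k-th neighbour in Wilson
  editing prefer the lower row index; a plurality tie among neighbour
  labels keeps the row. All deterministic, all documented here because the
  underlying definitions are silent on ties.
* **Constant columns.** The z-score maps σ = 0 columns to zeros instead of
  raising — constant features are uninformative and real clinical tables
  contain them. A column that is constant in value but not in floating
  point (e.g. repeated 3.14, whose computed mean differs from 3.14 by one
  ulp) is clamped to σ = 0 when its std is below 1e−12 relative to the
  mean's magnitude; otherwise the z-score would amplify pure rounding
  noise to O(1) values.

## Preprocessing pipeline

* **Population z-score**: per attribute, (x − μ)/σ with the divide-by-N σ.
* **Wilson's edition** (ENN, k = 3 by default): every row is judged
  against the *original* set under Euclidean distance and all failures are
  removed together (single simultaneous pass); sequential removal would
  make the result order-dependent.
* **Missing values**: either row deletion, or class-conditional imputation
  — class mean for continuous attributes, class mode (ties to the smallest
  value) for categorical ones. A (class, attribute) pair with no observed
  value is an error naming the pair.

By default normalization statistics, editing and imputation are computed
on the full dataset before cross-validation, mirroring the usual
dataset-then-CV experimental pipeline; this leaks test-fold information
into the statistics. A per-fold mode (`per_fold_prep=True` /
`--per-fold-prep on`) fits normalization on training rows only and edits
training rows only. Imputation and row deletion always run up front:
class-conditional imputation consumes the row's own class label and has no
leakage-free analogue for unlabeled queries. The stage *order* is the
user's list, so editing can run on raw or normalized features as desired.

## Validation protocol

Repeated stratified k-fold CV, defaults k = 10, r = 10. Within each class
the shuffled instances are dealt round-robin to folds, so per-class
per-fold counts differ by at most one and remainder instances land in the
lowest-indexed folds. The grand mean averages all r × k success rates
(equivalent to averaging per-repeat means, since every repeat has the same
number of folds). A single master seed drives the repeats through
`numpy.random.SeedSequence(seed).spawn(r)`: repeat i is reproducible in
isolation and the full run is bit-deterministic. When the smallest class
has fewer instances than folds the run proceeds with a warning and
degraded stratification.

## Synthetic data

The generator emulates the features of the clinical UCI-style tables the
pipeline targets: multi-class real-valued patterns with class-dependent
means (isotropic Gaussians — richer covariances would add nothing to the
operator coverage), planted missing-value markers, categorical columns
via the readers, exactly symmetric tie fixtures, and planted boundary
outliers. Default blob conditions: two classes of 50 patterns each;
"separable" means 20 units apart at σ = 1 (a 10σ gap, under which CV
accuracy is 100% by construction), "overlapping" means 1.5 units apart.
A Breast-Cancer-shaped missing-value fixture uses 699 rows with exactly
16 missing-bearing rows (683 survivors after deletion), matching the
published row arithmetic of that dataset.

Planted outliers copy the coordinates of a distinct genuine row of a
foreign class. Under the lower-index distance tie rule this *guarantees*
that at least two of the flip's three nearest neighbours carry the foreign
label (its zero-distance host, plus — for any co-ranked planted row — that
row's own lower-indexed host), so Wilson editing removes every planted
flip deterministically, not merely with high probability.

What passing these tests does **not** show about real data: the generators
are isotropic, unskewed and feature-independent, so they say nothing about
performance under correlated features, class imbalance beyond the ratios
tested, or non-Euclidean attribute scales; the published clinical datasets
exercise all three.

## Problem sizes

The shipped tests and the acceptance script use 40–200-pattern datasets,
50-dataset oracle sweeps, and 10×10-fold CV on 100 patterns — sizes at
which every oracle (O(p²) ENN replay, per-component learning-rule replay,
exhaustive score loops) is exact and fast, chosen so the whole suite runs
in seconds.

## Known limitations

* CHAT-OHM's inner-product similarity is not translation-invariant per
  *feature scale*: z-scoring changes its geometry, and on heavily
  overlapping classes the 1-NN-like rule can trail CHAT's class-sum rule
  (visible in the worked example). This mirrors the method's sensitivity
  to outliers and motivates the Wilson-editing stage.
* Stored models embed only z-score statistics, not editing/imputation
  decisions (those change the training set, not the query path).
* ARFF support is read-only.
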