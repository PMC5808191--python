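# Methods

This note documents the models, conventions and numerical choices the
package implements, and what its synthetic benchmark does and does not
establish.

## From time series to graph features

Functional connectivity is the absolute Pearson correlation
|r<sub>ij</sub>| between regional mean signals; the sign of a
correlation is deliberately discarded, so anti-correlated regions count
as connected.  Subjects need at least 3 time points and no
constant-signal region (such regions are rejected by name rather than
silently producing NaNs).

The binary brain graph keeps an edge where |r| **strictly exceeds** the
threshold τ (default 0.25).  The strict rule matters only for entries
exactly equal to τ; it is fixed so that results are reproducible, and τ
is configurable.

Four node-wise metric families are computed on the binary graph:

- **Degree** k<sub>i</sub>: row sums of the adjacency matrix.
- **Shortest path** d<sub>ij</sub>: unweighted hop counts (breadth-first
  search).  Distances are computed on the thresholded graph, not on
  correlation weights; a weighted variant is out of scope.  Pairs with
  no connecting path receive the finite sentinel **N** (the node
  count).  A finite value is required because distances become SVM
  features, and N strictly dominates every achievable path length
  (≤ N−1).  Raising τ can only remove edges, so degrees never rise and
  distances never fall — the sentinel sorts as the largest distance,
  preserving this monotonicity.
- **Clustering coefficient** C<sub>i</sub> = 2t<sub>i</sub> /
  (k<sub>i</sub>(k<sub>i</sub>−1)), with t<sub>i</sub> the edge count
  among i's neighbours.
- **Local efficiency** E<sub>loc,i</sub>: the Latora–Marchiori form,
  the mean of 1/d<sub>jh</sub> over ordered neighbour pairs of i, with
  d computed on the subgraph induced by the neighbours (i itself
  removed); unreachable neighbour pairs contribute 0.

Nodes of degree < 2 get C<sub>i</sub> = E<sub>loc,i</sub> = 0 rather
than NaN, so feature vectors never contain missing values.

The canonical feature order — degrees, upper-triangle shortest paths in
row-major (i<j) order, local efficiencies, clustering coefficients —
gives 3N + N(N−1)/2 features (4,275 at N = 90).  Fixing the order is
what makes feature-frequency counting and region-weight mapping
reproducible; `FeatureIndexMap` is the bijection between flat indices
and (metric family, region(s)) descriptors.

## Dataset splitting

The train size is ⌊0.7·n⌋ (58/26 at n = 84).  Splits are stratified by
diagnosis by default — on cohorts this small a purely random split can
leave a class nearly absent from the test set — and stratification can
be disabled to mimic a plain random split.

## The random SVM cluster

Each base classifier is an RBF SVM fitted on s training subjects and f
features sampled without replacement (defaults B = 500, s = 50,
f = 62).  Subject draws that contain a single class are rejected and
redrawn (up to 100 attempts) so B stays fixed.  All random subsets come
from one seeded generator: identical configurations reproduce
bit-identical clusters.

**Standardization.**  Features are z-scored with training-set statistics
by default (zero-variance features get scale 1).  Raw graph features
mix scales — integer degrees up to N−1, distances up to N, efficiencies
in [0,1] — and an RBF kernel with a fixed width is scale-sensitive.
Standardization can be disabled.

**Kernel width convention.**  The width parameter σ (default 3) enters
through the root-mean-square feature difference:

    K(x, z) = exp( − mean_f (x_f − z_f)² / (2σ²) ),

i.e. scikit-learn's γ = 1/(2σ²f) for an f-feature subspace.  The
conventional summed form K = exp(−‖x−z‖²/(2σ²)) is available as
`kernel_distance="euclidean"`.  The RMS form is the default for a
concrete numerical reason: over f = 62 standardized features the
expected squared Euclidean distance between two subjects is ≈ 2f ≈ 124,
so the summed convention at σ = 3 drives every off-diagonal kernel
entry to e<sup>−6.9</sup> ≈ 10<sup>−3</sup>.  The Gram matrix is then
numerically degenerate and each hard-margin base SVM collapses toward a
constant classifier; measured base-classifier accuracies sit at chance
even when a perfectly separating feature is in the subspace.  The RMS
convention makes "width 3" mean three standardized units *per feature*,
independent of how many features a base classifier drew, and restores
the base SVMs' ability to exploit informative features.

**Penalty.**  The effectively-infinite (hard-margin) penalty is the
finite 10<sup>10</sup>; numerical solvers need a finite value, and at
this magnitude no margin violations survive on separable subsets.  It
is configurable.

**Voting.**  Each base SVM votes with its own feature subset; the
ensemble label is the majority.  Because B may be even, even splits are
broken by the sign of the summed real-valued decision outputs, and an
exact zero falls back to +1.  Both rules are deterministic; votes
always satisfy (+1 votes) + (−1 votes) = B.

**Size sweep.**  Accuracy as a function of B (default sizes 5, 10, …,
700) builds an independent, freshly seeded cluster per size; the
optimal size is the smallest attaining the maximum.  A cheaper
`prefix` mode evaluates nested prefixes of one large cluster instead.

## Feature selection

Base classifiers are ranked by individual test accuracy (stable sort:
ties keep construction order).  The top K = 100 classifiers' subsets
form a K × f index matrix; entry frequencies are counted (the counts
always sum to K·f) and the M = 400 most frequent features — frequency
ties broken by ascending feature index — are the "important features".

The optimal feature set is found by rebuilding a full cluster for each
prefix length q (default 70, 72, …, 400, of which values exceeding the
number of distinct counted features are dropped), with per-classifier
feature subsets drawn from the first q important features only; sample
subsets are freshly drawn per q from a seed derived deterministically
from the configuration seed.  The optimal q is the smallest attaining
the maximal accuracy, and the full (q, accuracy) curve is emitted for
inspection.  Region weights count how many selected features touch each
region; pairwise (shortest-path) features credit both endpoints, so
weights sum to (#unary features) + 2·(#pair features).

**Evaluation modes.**  The published protocol ranks classifiers and
selects q on the same held-out subjects whose accuracy it then reports.
That is a test-set leakage pattern: selected-feature accuracies are
optimistically biased.  `mode="paper"` reproduces it exactly and
`mode="honest"` carves a validation subset out of the training set for
ranking and the q search, reserving the test set for one final
evaluation; both modes announce themselves in the run log.

## Demographic comparisons

Gender composition uses the Pearson chi-square test on the 2×2 table
**without** Yates continuity correction (df = 1); on the reference
counts [[41, 4], [33, 6]] the uncorrected test gives p = 0.359 while
the corrected one gives 0.563, so the uncorrected form is the one that
matches the reference analysis.  Age uses the pooled-variance
two-sample t-test from summary statistics (df = n₁+n₂−2), with Welch's
form as an option.  From the rounded reference summaries (13.4 ± 2.4,
n = 45 vs 12.9 ± 1.7, n = 39) the pooled test gives p = 0.281;
reproduction of the reference 0.278 is only possible to ±0.01 because
the inputs themselves are rounded to one decimal.

## The synthetic cohort generator

Each subject's T × N series is drawn from a zero-mean multivariate
normal.  Both groups share a background correlation matrix with modular
(community) structure: N regions in `n_modules` contiguous blocks
(default 9 blocks of 10), correlation 0.45 within a block and 0.08
between blocks.  The patient group additionally has `effect_size`
δ (default 0.4) added to the correlation of `n_planted_edges` (default
30) randomly chosen region pairs.  Study-scale defaults are N = 90,
T = 110, 40 + 40 subjects.

The modular background was chosen over a uniform correlation level for
two reasons.  Real functional connectomes are strongly modular, with
correlations spread well above and well below any practical threshold.
And a uniform level near τ makes every one of the N(N−1)/2 edges a
maximal-variance coin flip, which puts the thresholded graph near its
percolation threshold: path-length features then fluctuate enormously
and coherently within subject, and no classifier — however good — can
recover the planted effect reliably.  A uniform background remains
available via `n_modules=1`.

Effects are planted in the *covariance*, not in graph metrics directly,
so group differences in the features emerge only through the same
correlation → threshold → metrics pipeline applied to real data.  If a
planted increment breaks positive definiteness the matrix is repaired
by eigenvalue clipping (floor 10⁻⁶) followed by rescaling to unit
diagonal, and the Frobenius norm of the change is logged.  White noise
of standard deviation `noise_sd` (default 0, keeping planted
correlations exact on average) can be added on top.

What the simulation does *not* emulate: hemodynamics, temporal
autocorrelation, motion artifacts, site effects, or heterogeneous
subject-level connectivity strength.  Passing the planted-effect
benchmark therefore shows that the pipeline recovers group differences
expressed through connectivity under idealized noise — not that any
particular accuracy carries over to real cohorts.

## Problem sizes used in the automated checks

The test suite exercises ensembles of up to a few hundred classifiers
on reduced cohorts (20–30 regions) and runs the study-scale
configuration (N = 90, T = 110, 40 + 40 subjects, B = 500) for ten
planted and ten null seeds; the optimal-q search in the automated
checks uses the coarsened grid 70, 100, …, 400.  These sizes keep a
full run of tests plus the reproduction script to a few minutes while
still covering the defaults end to end; the full q grid (step 2) and
the full size sweep (5, …, 700) remain available through the library
and CLI.

## Known limitations

- Only the RBF kernel, unweighted voting and two-class problems are
  supported; there is no probability calibration or class weighting.
- Shortest paths are hop counts on the thresholded graph; weighted
  graph metrics are out of scope.
- Feature selection inherits the frequency-counting statistic's
  weakness: with K·f counted slots spread over thousands of features,
  top frequencies are small integers and carry large sampling
  variance.  The honest evaluation mode quantifies, but does not
  remove, this instability.
- The demographics module works from summary statistics only; it does
  not ingest subject-level covariates.
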