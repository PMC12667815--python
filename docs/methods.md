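# Methods

This note documents the models and procedures implemented in `divsel`, the
parameter conventions that matter, the numerical choices made where the
design was genuinely open, and what the synthetic fixtures do and do not
demonstrate.

## Problem setting

All selectors consume a feature matrix `X` of shape `(s, d)` — real-valued
descriptors or binary fingerprints — or, for the purely distance-based
methods, a precomputed symmetric distance matrix `D` of shape `(s, s)`
(validated: symmetric within 1e-10, zero diagonal, finite, nonnegative).
A selection is an ordered list of distinct row indices; order is the
selection order, which matters because sphere-exclusion selectors truncate
to the requested size.  Indexing is 0-based everywhere, and every argmax/
argmin tie breaks to the lowest index, so all deterministic selectors are
exactly reproducible and testable.

Built-in metrics: `euclidean`, `minkowski:p` (p ≥ 1), `tanimoto-distance`
(1 − a/(a+b+c)), and `modified-tanimoto-distance`.  Arbitrary user callables
are accepted; because a silently asymmetric metric corrupts every downstream
selector, user metrics are verified for symmetry over the full matrix (the
matrix is already O(s²) to build, so the check is free asymptotically) and
the diagonal is clamped to exactly zero.

## Distance-based selectors

**MaxMin** starts from the dataset medoid (argmin of row sums of `D`; ties
to the lowest index) or user-supplied indices, then repeatedly adds the
candidate maximizing the minimum distance to the selected set.  **MaxSum**
replaces the criterion with the sum of distances.  Both maintain the
per-candidate criterion incrementally, so a run is O(s·n) after the matrix
is available.  Greedy MaxMin is a 1/2-approximation of the max-min
dispersion optimum — it is *not* guaranteed to dominate every same-size
subset, and on small uniform clouds a lucky random subset occasionally edges
it out; the test suite therefore asserts the provable factor-2 bound plus
dominance over the overwhelming majority of random subsets rather than
dominance over all of them.

**OptiSim** starts at a reference sample (medoid by default), permanently
excludes everything within radius `r` of any selected sample, and at each
step draws a uniform random subsample of size `k` (without replacement,
seeded; all survivors when fewer than `k` remain) from the remaining
candidates, picking the one with the greatest minimum Minkowski p-norm
distance to the selected set.  **DISE** (directed sphere exclusion) sorts
samples by ascending p-norm distance from the reference (ties to the lower
index) and walks the list, accepting a sample iff no earlier selection's
exclusion sphere covers it.  Defaults: `p = 2`, `k = 10`, reference =
medoid.  Distances are computed on demand from features; the full s×s
matrix is never materialized inside the exclusion loops (the medoid
reference is the one step that needs it).

With `k ≥ s` and `r = 0`, OptiSim reduces exactly to MaxMin — used as an
equivalence oracle in the tests.

### Radius tuning

Neither sphere-exclusion method has a closed-form radius for a target size
`n`, and the natural stopping size is (weakly) decreasing in `r`.  The
radius is therefore tuned by bisection on `[0, r_hi]` with 50 iterations,
where `r_hi` is twice the maximum distance to the reference (a triangle-
inequality bound on any pairwise distance).  The invariant maintained is
that the lower bracket always yields ≥ `n` natural selections, so the final
sequence is truncated to the first `n` in selection order.  If the user
supplies `r` explicitly, it is used directly when it already yields ≥ `n`
samples (so fixed-radius runs behave as stated) and otherwise serves as the
upper bracket.  A fallback tops up an undersized selection with the
unselected samples nearest the exclusion-zone boundaries; with the zero
lower bracket it is unreachable in practice but kept for safety.  Each
candidate radius re-runs the seeded generator from the same state, so the
tuned result is deterministic per seed.

## Partition-based selection

Four binning schemes over the observed ranges: equisized (uniform edges) or
equifrequent (empirical quantile edges), each either independent across
dimensions or dependent (dimensions processed in natural column order; each
dimension's edges are recomputed within every parent cell of the previously
processed dimensions, so feature order affects the outcome — an inherent
property of dependent binning, not an artifact).  The last interval is
right-closed so maxima fall in the last bin; a constant dimension collapses
to a single degenerate bin.  Default bins per dimension: `ceil(n^(1/d))`,
giving a grid of roughly `n` cells.

Selection visits non-empty cells round-robin in ascending occupancy (ties
by lexicographic cell id), so rare regions are guaranteed representation
before populous ones contribute twice.  Within a cell the pick is the cell
medoid under euclidean distance — deterministic and testable; pass
`random_in_cell=True` for a seeded uniform draw instead.  Empty cells are
ignored entirely.

## Counter-based (n-ary) similarity

For binary vectors the classic pairwise indices are functions of the
contingency counters `a` (both on), `d` (both off), `b + c` (mismatches),
`p = a + b + c + d`.  Two set-level generalizations avoid the O(n²) cost of
averaging all pairs:

- **iSIM** aggregates exact pair counts from column sums `k_j`:
  `a = Σ k_j(k_j−1)/2`, `d = Σ (s−k_j)(s−k_j−1)/2`, mismatches
  `Σ k_j(s−k_j)`, `p = d_cols·C(s,2)`.  For indices linear in the counters
  (Russell–Rao, Sokal–Michener) this equals the mean pairwise similarity
  *exactly*; for the others it is a close surrogate.  Binary input only —
  non-binary input is a hard error.
- **eSIM** classifies each column by its majority margin `Δ_j = |2k_j − s|`:
  1-similarity if `2k_j − s > t`, 0-similarity if `s − 2k_j > t`, else
  dissimilarity, with coincidence threshold `t = 0` (strict majority) by
  default.  Weighted counters use `w(Δ) = Δ/s` for similarity columns and
  the complementary fraction `1 − (Δ − s mod 2)/s` for dissimilarity columns
  (`weight_scheme="fraction"`; `"none"` counts every column as 1).  Weighted
  counters enter the index *numerators* while raw column counts enter the
  *denominators* — the structure of the extended-similarity family.  This
  matters: putting weights in the denominators as well makes every index
  collapse to {0, 1} whenever no dissimilarity columns exist (all odd-size
  binary sets at t = 0, and almost surely all continuous data), which
  degenerates greedy selection into tie-breaking.  At `s = 2` all weights
  are 1 and every index reduces exactly to its pairwise formula.

The registry holds 16 indices: Austin–Colwell, Baroni–Urbani–Buser,
Consonni–Todeschini 1–4, Faith, Gleason, Jaccard, Jaccard 0-variant
(3d/(3d+b+c), the off-bit mirror of Jaccard 3a/(3a+b+c)), Jaccard–Tanimoto,
Rogers–Tanimoto, Russell–Rao, Sokal–Michener, Sokal–Sneath 1 and 2.
Zero-denominator rule: an undefined ratio evaluates to 1 when the
comparison has no dissimilarity columns (e.g. two identical all-zero
fingerprints) and 0 otherwise — continuity with the identity convention and
crash-freedom on sparse fingerprints.

**Modified Tanimoto** blends the on-bit Tanimoto `T1 = a/(a+b+c)` and the
off-bit analogue `T0 = d/(d+b+c)` with weights set by the mean on-bit
fraction p̄ of the pair: `MT = ((2−p̄)/3)T1 + ((1+p̄)/3)T0`.

**Similarity→distance** conversions: `reverse` (1−s), `squared-root`
(√(1−s)), `reciprocal` (1/s − 1; similarity 0 is a hard error pointing to
the other methods).  Converted matrices get an exactly-zero diagonal.

### NSimilarity selection

Greedy: starting from a user-defined index or the most outlying sample (the
one whose removal leaves the most self-similar remainder — an O(s) scan
using the counters), each step adds the candidate whose inclusion minimizes
the set-level similarity, ties to the lowest index.  The counter engine is
an explicit switch (`engine="esim"` default, `"isim"` for binary data).
Real-valued data is supported via `preprocess=True`, which min-max scales
each column to [0, 1] **once over the full matrix**; candidate subsets are
always scored in that fixed frame.  (Rescaling each candidate subset by its
own range collapses every pair to exact corners and destroys the
selection — a failure mode discovered and fixed during development.)
Constant columns map to 1, i.e. fully coincident.

On low-dimensional point clouds this selection lands on convex-hull
vertices more often than uniform random subsets, consistent with the
peripheral behavior expected of average-similarity minimizers; the effect
is a tendency, not a guarantee, and is tested against the exact expectation
of the random baseline.

## Diversity measures

Directions follow the standard conventions: higher log-determinant, Shannon
entropy and explicit diversity index ⇒ more diverse; lower WDUD, Gini and
hypersphere overlap ⇒ more diverse.

- **log-determinant**: `log det(X_sel X_selᵀ + I)`, evaluated on the smaller
  of the two Gram factors (Sylvester's identity) via `slogdet`.  The
  identity regularization keeps the value defined and ≥ 0 for `n > d`,
  duplicated rows and all-zero input alike.
- **Shannon entropy** (binary only): `Σ_j h(p_j)` bits, `p_j` the on-bit
  fraction of column j, `h(0)=h(1)=0`; range [0, d].
- **Explicit diversity index** (binary only): `SDI = (1 − NAT)/(0.8047 −
  0.065 ln n)` with NAT the mean nearest-neighbor Jaccard–Tanimoto
  similarity, `CR = −log10(n/cs³)`, `EDI = (SDI + CR)/√2`, reported as
  `100·(tanh(EDI/3)+1)/2 ∈ (0, 100)`.  The constants follow the published
  form of the index; `cs` is the cluster/compound-count parameter.
- **Gini coefficient** (binary only): rank-weighted form
  `2·Σ j·c_(j)/(d·Σc) − (d+1)/d` over ascending-sorted column counts;
  equals the mean-absolute-difference Gini exactly.  All-zero matrices are
  a hard error (undefined share vector).
- **WDUD**: per feature, min-max normalize to [0, 1] and integrate
  `|F(t) − t|` exactly piecewise over the sorted sample (`F` the empirical
  CDF); report the mean over features; range [0, 0.5].  A constant feature
  is treated as a point mass at 0.5, contributing 0.25 — zero spread is
  penalized without special-casing downstream means.
- **Hypersphere overlap** (relative: needs the full matrix): features are
  normalized by the *full* data's per-column range; each selected point
  carries a sphere of radius `r`, and the score is the pairwise term
  `Σ_{d_ij<2r}(1 − d_ij/(2r))` plus the boundary penalty
  `Σ_i Σ_j max(0, 1 − e_ij/r)` with `e_ij` the distance to the nearer wall
  of dimension j.  The linear pair term is a surrogate for the exact
  hypersphere lens volume, which is deliberately out of scope.  Default
  `r` = half the mean nearest-neighbor distance of the full normalized
  data.  Note the boundary penalty is intentional: subsets hugging the data
  envelope pay for spilling outside it, so a "spread" subset sitting exactly
  on the extremes can score worse than a moderately interior one.

## Stratified selection

Passing integer labels (as `y` in `fit`, `--labels` on the CLI) runs the
configured selector independently within each class under proportional
quotas: largest-remainder (Hamilton) apportionment of `n` over class sizes,
then any class left at zero is raised to 1 (taking the seat from the
largest current holder) provided `n ≥` the number of classes; quotas are
capped at class sizes with the surplus redistributed by largest remainder.
When `n <` the number of classes a warning is issued and the `n` largest
classes receive one sample each.  For class sizes (98, 19, 10, 9, 7, 2) and
`n = 9` the quotas are (4, 1, 1, 1, 1, 1).

## Synthetic data: what it emulates, and what it does not

- `gaussian_blobs` — isotropic labeled clusters; the 2-D demonstration
  surface.
- `random_fingerprints` — i.i.d. Bernoulli bits.  Real fingerprints have
  correlated, sparse, popularity-skewed bits; these do not, so tests on
  them validate counter algebra and selector mechanics, not chemical
  realism.
- `biased_class_dataset` — six Gaussian classes of sizes 98/19/10/9/7/2
  (total 145) on a circle of radius 10 with unit spread: well-separated by
  construction, standing in for a curated set of 145 organic compounds in
  six chemical classes.  It shows that distance-based selection covers rare
  classes without label information; it cannot show how fingerprint
  geometry affects that coverage.
- Four-well potential: `V(q1,q2) = (q1²−1)² + (q2²−1)² + 0.08·q1 + 0.16·q2`,
  four minima near (±1, ±1) of unequal depth (deepest near (−1,−1), a
  shallow one near (+1,+1)), all inside [−3, 3]².  The tilts were chosen so
  the mild-bias sample covers all basins while the strong bias nearly
  misses the shallow one; this is a stand-in with the same qualitative
  structure as published four-well forms, not a reproduction of any
  specific parametrization.
- `mc_boltzmann_sample` — draws a uniform pool over [−3, 3]², weights each
  point by `exp(−1.5·k·(V − V_D))` ∈ (0, 1] (`V_D` the deepest minimum's
  energy, found by Nelder–Mead from the four quadrant seeds), and samples
  the output *without replacement* with probability proportional to the
  weight — an importance-weighted selection giving an exact target count,
  chosen over a Metropolis chain for determinism and simplicity.  Defaults
  are desk-scale (pool 10⁵, output 10³) and flag-overridable to the
  full-scale 10⁷/10⁴ setting.
- `redundant_and_diverse_points` / `_fingerprints` — paired same-size sets
  for direction checks.  The redundant member emulates a poor *selection*
  (a dense clump plus a few stragglers that set the range; or
  prototype-mutated fingerprints), the diverse member a good one
  (near-uniform coverage; independent bits).  A plain tight-vs-wide Gaussian
  pair would not do for WDUD, which is shift/scale invariant: after
  self-normalization a tight blob looks as (non)uniform as a wide one.  The
  clump-plus-stragglers shape is what redundant selections of real data
  look like once normalized.

## Numerical conventions

- Ties: always to the lowest index (medoid, greedy argmax/argmin, sorted
  orders via stable sort).
- Seeds: every stochastic component takes an explicit seed
  (`numpy.random.default_rng`), recorded in the selection provenance.
- Degenerate inputs: single samples, constant columns/dimensions, all-zero
  fingerprints and duplicated rows are defined cases (documented per
  measure above), not errors, except where the quantity is genuinely
  undefined (Gini of an all-zero matrix, EDI of a single sample,
  reciprocal conversion at similarity 0, iSIM on non-binary data).
- Float comparisons in greedy loops use a 1e-15 margin so exact ties break
  by index rather than by accumulation order.

## Problem sizes

Tests and the acceptance script run at desk scale — hundreds of samples,
pools of 10⁵ points, 100–200 randomized oracle instances — chosen so the
full suite completes in well under a minute while every check still
exercises the property it names at non-trivial size.

## Known limitations

- OptiSim follows the two-step subsample description (no recycling bin for
  skipped candidates, which some older formulations keep).
- iSIM values for non-linear indices are surrogates for the mean pairwise
  similarity, not exact; only Russell–Rao and Sokal–Michener are exact.
- The hypersphere pair term is linear in distance rather than the exact
  lens volume.
- eSIM on continuous data inherits the coarseness of column-sum counters:
  in very low dimension the objective has few degrees of freedom, and
  selections are driven by column means rather than geometry.
- No fingerprint generation from molecular structures: the package is
  feature-matrix-in, indices-out by design.
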