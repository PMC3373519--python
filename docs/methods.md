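# Methods

`morphoclade` chains four analysis stages that together support a
morphology-based taxonomic revision: elastic comparison of anatomical
outlines, ordination of the resulting dissimilarities, maximum-parsimony
phylogenetics on a discrete character matrix, event-cost ancestral-range
reconstruction, and allometric body-size regression. This note records
the models, the numerical choices, and what the synthetic data do and do
not establish.

## Elastic outline comparison (SRVF)

An outline is an ordered planar point sequence; closed outlines join the
last vertex to the first. A curve β(t) is represented by its square-root
velocity function q(t) = β̇(t)/√‖β̇(t)‖, which removes translation by
construction; scale is removed by rescaling q to unit L2 norm. Unit-norm
SRVFs live on a sphere, where the geodesic distance between two curves is

    d(q1, q2) = arccos ⟨q1, O (q2 ∘ γ) √γ̇⟩,

minimized over rotations O ∈ SO(2), monotone reparameterizations γ, and
(for closed outlines) the cyclic starting point of the parameterization.
Reflections are excluded by default because anatomical sidedness is
meaningful; `allow_reflection=True` enlarges the group to O(2).

Numerical scheme:

- Curves are resampled to m uniformly spaced arc-length points (default
  m = 128) before the SRV transform; q is computed by central
  differences (cyclic for closed curves).
- Rotation is solved in closed form by the 2×2 Kabsch/SVD alignment.
- Reparameterization is a dynamic program over monotone lattice paths on
  the m×m grid with local slopes restricted to [1/4, 4] (step set of
  coprime moves up to 4), which prevents degenerate warps. Ties break
  toward the diagonal. The DP objective has been checked against
  exhaustive enumeration of all monotone lattice paths (5,294,857 paths
  at m = 16).
- Closed outlines are re-cut at a canonical vertex (the point farthest
  from the vertex centroid) before any comparison. The DP anchors γ at
  the curve seam, so without a canonical cut the optimum would depend on
  where the input happened to start. The relative starting point of the
  second curve is then searched over all m integer cyclic shifts; the
  best few local maxima of the rotation-aligned inner product are each
  refined to fractional arc-length offsets by bounded 1-D minimization,
  because integer-shift resolution alone leaves a seam misalignment of
  order 1/(2m) that is visible at the 1e-3 tolerance.
- The alternation (seed → rotation → reparameterization) runs to an
  improvement below 1e-8 or 20 rounds. The procedure warps the second
  curve toward the first and is therefore asymmetric; both orderings are
  evaluated and the smaller distance returned, making the reported
  distance exactly symmetric.
- The computed distance is an upper bound on the true elastic geodesic
  (the optimization is over a restricted family), which is why the
  triangle-inequality property is asserted with a 1e-3 slack.

The treatment is the open-curve pre-shape sphere with an explicit seed
search, not an exact closed-curve projection; exact closed-curve
geodesics are out of scope.

The length/width ratio of an outline is the ratio of its extents along
the two principal axes of the vertex scatter (larger over smaller). The
three-bin character coding uses cut points 1.85 and 2.85, with the
middle bin the closed interval [1.85, 2.85] — a boundary ratio falls in
the middle bin, matching the diagnosis wording "between".

## Non-metric multidimensional scaling

Dissimilarities enter only through ranks. Each iteration fits monotone
disparities δ̂ to the configuration distances by isotonic regression and
moves the configuration with a Guttman transform; misfit is Kruskal
stress-1, √(Σ(d−δ̂)²/Σd²). Iteration stops at the first step that fails
to reduce stress-1, so the reported per-iteration stress sequence is
non-increasing. The first restart starts from the classical (Torgerson)
metric solution with eigenvector signs canonicalized (largest-magnitude
coordinate positive, for label equivariance); the remaining restarts
(default 8 in total) start from seeded Gaussian configurations. A
configuration with zero spread is assigned stress 1.0. Default
dimension p = 2, matching the two plotted ordination axes.

## Parsimony

Tree length is equally weighted Fitch parsimony: per character, the
intersect-else-union bottom-up pass over an arbitrary rooting of the
unrooted binary topology; polymorphic cells enter as their state set and
missing/inapplicable cells as the full set. Characters are unordered by
default (ordered flags are carried per character for matrix
compatibility).

- CI = Σmᵢ/L with mᵢ = (number of distinct scored states − 1);
  RI = (Σgᵢ−L)/(Σgᵢ−Σmᵢ) with gᵢ = (scored taxa − frequency of the most
  common state). Polymorphic cells are resolved to their globally most
  frequent member state for both mᵢ and gᵢ. Constant and autapomorphic
  characters stay in the sums (RI is reported as undefined when
  Σg = Σm). Values are rounded only at reporting.
- Search: random addition sequences (greedy stepwise insertion in a
  seeded random order, ties broken at random) followed by hill-climbing
  through SPR or TBR rearrangements, keeping up to `hold` equally
  parsimonious trees per replicate; distinct optima are pooled over
  replicates and deduplicated by their unrooted split sets. The TBR
  neighborhood is the union of internal-edge bisection/reconnection
  moves and all SPR moves (which cover pendant-edge bisections).
- Bootstrap support: characters resampled with replacement (weight
  vector per replicate), a reduced search per replicate, and a split is
  counted when it appears in the strict consensus of that replicate's
  best trees; support is the percentage over replicates.
- Bremer decay: converse-constraint searches — hill-climbing restricted
  to trees lacking the clade, with start trees pushed off the clade by
  an NNI across the corresponding edge when needed; decay is the
  constrained optimum minus the global optimum, capped at
  `max_extra_steps`.
- An outgroup is used only to root trees for display; scoring and search
  are unrooted throughout.

Default search parameters mirror the published analysis (10,000 RAS with
TBR holding 10; bootstrap with SPR at 25 RAS), but tests and the
acceptance script use reduced replicate counts (5 RAS, 8-taxon matrices)
chosen so each search still finds the global optimum on matrices of that
size, verified against exhaustive topology enumeration at n ≤ 7.

## Dispersal-vicariance reconstruction

Ranges are non-empty subsets of a fixed area list (bitsets; the bundled
analysis uses Europe, Asia, northern North America, southern North
America). Speciation is free when it duplicates a single-area range or
partitions a widespread range into two disjoint non-empty subsets — any
bipartition is allowed, not only single-area splits (`single-area-split`
compatibility with stricter implementations is available by setting
maxareas and restricting candidate splits is not needed for the bundled
analyses). Dispersal and extinction cost one per area gained or lost
along a branch, i.e. the branch cost between ranges S and G is the
symmetric-difference size |S△G|.

The reconstruction is an exact dynamic program over all candidate ranges
per node (subsets of size ≤ maxareas, default all areas): an upward pass
computes the best subtree cost for every (node, range) pair, a downward
pass the best cost of the rest of the tree, and a range is reported at a
node when up + down equals the global optimum — so every co-optimal
distribution is reported, mirroring classic DIVA's alternative
reconstructions, in deterministic bitset order. Equality of both the
optimal cost and the per-node optimal sets has been verified against
exhaustive enumeration of all internal-node assignments on trees with
≤ 6 leaves and ≤ 3 areas.

## Allometric regressions

Both body-size regressions are ordinary least squares on untransformed
lengths (the published scatterplots have linear axes; a log-log option
is provided). The residual standard deviation uses n−2 degrees of
freedom; prediction intervals use the t distribution for a new
observation. Two models are chained: preserved distal humeral portion →
complete humerus length (both mm), then humerus (mm) → body length (m).
The synthetic generators default to the anchor relationships implied by
the published point estimates — slope 803/723 ≈ 1.111 for the first
regression and 12.5/803 ≈ 0.01557 m/mm for the second, both with zero
intercept — because the underlying specimen-level scatter is not
printed; those two anchors are reproduced, not independently tested.

## Synthetic data

- Outlines: a tear-drop family x(t) = cos t, y(t) = w·sin t·sin^p(t/2)
  (pointedness p = 2 by default), anisotropically rescaled so the
  measured length/width ratio equals the target exactly, then perturbed
  by band-limited periodic noise (RMS amplitude as a fraction of outline
  scale, default 2%) and jittered by random rotation, translation,
  log-normal scale, and cyclic re-cutting. Default groups emulate the
  narial-outline contrast: ratio 2.4 versus 3.2. Low-frequency noise
  moves the extreme points, so measured ratios scatter around the
  target; the truth table records the exact pre-noise ratio.
- Matrices: a known random topology; each character receives a fixed
  budget of state changes placed on distinct random internal edges
  (default budget 1, which makes the matrix homoplasy-free and every
  character parsimony-informative, emulating a curated morphological
  matrix; pendant edges are included on request). Missing data are
  masked per cell at a configurable rate, never leaving a taxon fully
  unscored.
- Ranges: forward simulation down a random rooted topology with free
  duplication/vicariance at nodes and a prescribed number of dispersal
  (area gain) and extinction (area loss) events on random branches;
  inapplicable events (dispersal into a full range, extinction of a
  single-area range) are logged and skipped, and the trace records every
  event, so the realized event count bounds the inferred cost.
- Allometry: y = a + bx + N(0, σ²) with x uniform on a configurable
  range (defaults spanning the printed humeral-length table).

All generators are pure functions of configuration plus seed
(bit-reproducible).

What the synthetic data do not emulate: digitization noise correlated
along the outline, ontogenetic shape change, character correlation and
asymmetric state-change probabilities (no Mk-style branch lengths), or
time-stratified dispersal. Passing tests therefore demonstrate
correctness of the algorithms under the stated generative conditions,
not robustness to every property of real fossil data.

## Degenerate inputs and tie-breaking

Zero-length curves, collinear outlines, non-positive ratios, empty area
sets, non-binary nodes, and zero predictor variance raise explicit
errors. DP ties break toward the diagonal path; equal-length trees are
all retained up to `hold`; co-optimal DIVA ranges are ordered by bitset
value; stepwise-addition ties are resolved by the seeded generator.

## Known limitations

- The closed-curve distance is an upper bound (restricted optimization
  family), not the exact closed pre-shape geodesic.
- Heuristic searches are exact only in expectation; guarantees in the
  tests come from problem sizes where exhaustive verification is
  feasible.
- The published 286-character matrix is third-party data and is not
  redistributed; the published tree length/CI/RI benchmark runs only if
  a user supplies that file (see `tests/test_acceptance.py`).
- The bundled lambeosaurine topology and tip areas are transcribed from
  a published figure and support only qualitative checks.
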