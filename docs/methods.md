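# Methods

## The tracing model

`caatrace` reconstructs neuron morphology from a per-voxel neurite
probability map `P` (values in [0, 1], array order `(z, y, x)`).  The model
behind the method is simple and explicit: neurites are tubular, 26-connected
objects whose probability is high along their body, while true background is
confidently low; where the upstream predictor fails (dim, uneven or broken
stretches) the probability drops but rarely to exact zero.  Tracing therefore
splits into two regimes:

* **within a fragment** — deterministic voxel scooping over the thresholded
  segmentation, which needs no parameters beyond connectivity; and
* **across fragments** — an explicit bridging decision that imitates how an
  annotator judges two loose ends: are they close (distance term), genuinely
  distinct pieces (connectivity term), and joined by a corridor of residual
  probability (continuity term)?

### Initial segmentation

Background statistics are estimated from the voxels with probability below
0.5.  We use the sample mean and population standard deviation of that
sub-population directly rather than fitting a Gaussian to a binned histogram:
for a Gaussian background the two agree in expectation, and the moment
estimator is deterministic and bin-free.  The foreground threshold is
`μ_bg + λσ_bg` with λ = 3 by default (larger λ removes more background at the
cost of thinner fragments; the threshold is recorded in the output).
Components are labelled with full 26-connectivity; the seed of each component
is its first foreground voxel in lexicographic `(z, y, x)` scan order.

An all-background map yields an empty segmentation with a warning, not an
error.

### Voxel scooping

From the current node `TN_k` (center `c`), the *scooping distance* is the
largest Euclidean distance from `c` to an unvisited foreground voxel
26-adjacent to the current cluster.  The next point set is every unvisited
foreground voxel inside that ball that is 26-connected to the cluster through
unvisited foreground within the ball; it is split into 26-connected
sub-clusters, each becoming a child node at its centroid (this is how
branches arise).  Voxels are marked visited as scooped, so the tracer visits
each voxel at most once and necessarily halts.

Node radius is the Euclidean distance transform of the segmentation sampled
at the rounded node center, floored at 1 voxel.

Two refinements keep nodes on the medial axis (both on by default,
flag-controlled):

* **Seed refinement** (`refine_seeds`): the scan-order seed necessarily lies
  on the component surface; a greedy 26-neighbourhood ascent on the distance
  transform moves it to a local medial maximum before tracing, so the root
  node and the first scooped shells are centred.
* **Center smoothing** (`smooth_centers`): one radius-weighted averaging pass
  over each node and its tree neighbours.  Interior nodes already on the
  axis are unmoved (their neighbours are on the axis too); single-voxel
  residue clusters scooped at a tube's end cap — which sit on the surface by
  construction — are pulled back toward the axis.  On an intact radius-3
  test tube, every node lands within ~1.4 voxels of the true centerline.

### Gap bridging

When scooping exhausts at a node, candidate landing sites are the unvisited
foreground voxels inside a cube of half-width `2·d_t` around the node,
excluding the node's own component, grouped by component.  For each candidate
component the Chebyshev-closest pair `(c_p, s_p)` between the frontier and
the candidate voxels is scored:

* `d_score = 1` for `d ≤ d_t`, else `exp(−(d − d_t)/3)` — continuous at the
  boundary.  `d_t` (default 5, sensible range 4–5 voxels) is the only free
  parameter of the bridging rule.
* `c_score = 1` iff the two components differ — this is what prevents the
  tracer from "bridging" back into its own component at irregularities.
* `dpc_score = exp(−(d_ps − Σ CP(p_i))/d_ps)` over the interior voxels of the
  symmetric integer rasterization of the segment `c_p → s_p` (endpoints
  excluded: they belong to the fragments, not the gap; an adjacent pair
  scores 1).  `CP(p) = 1` for `p > t_l`, else `p`, with
  `t_l = min(0.1, median of the sub-0.5 population)` — credit is given to
  corridor voxels that look even weakly neurite-like.

A link is accepted when the product exceeds 0.5; the bridging node is placed
at `s_p`, its cluster is the winning component's unvisited voxels within
Chebyshev radius 1 of `s_p`, the component is absorbed (removed from the
pending seed queue), and scooping resumes there.

Ties break deterministically: higher score, then smaller distance, then
smaller component label; equal-distance closest pairs resolve to the
lexicographically smallest `s_p`, then `c_p`.

Two consequences worth knowing.  First, a *feasibility bound*: with a perfect
corridor the score is exactly `d_score`, so a gap is bridgeable iff
`d ≤ d_t + 3·ln 2 ≈ d_t + 2.08`; the candidate cube of half-width `2·d_t`
therefore provably contains every acceptable candidate.  Second, because
`t_l` is the background median, a corridor of plain background noise scores
`dpc ≈ exp(−1/2) ≈ 0.61`: nearby distinct fragments within `d_t` will
generally link unless their corridor is *worse than background* (exact
zeros).  The distance term, not the corridor term, is the main guard against
over-connection — which is why `d_t` is deliberately small.

### Tree building, pruning, SWC

Node types follow degree (leaf 1, path 2, branch > 2).  The stem is the
geodesically longest root-to-leaf path — "length-first" — computed exactly
rather than approximately, with ties broken to the smaller leaf id for
determinism.  Every remaining leaf contributes a branch running from its
attachment (branch) node to the leaf.  A branch whose node count below the
branch node is less than `l_num` (default 6, sensible range 5–10) is pruned;
since removal can demote a branch node and expose new stubs, pruning
iterates to a fixpoint.  The stem is never pruned.

SWC output renumbers ids depth-first from 1, maps array coordinates
`(z, y, x)` to SWC columns `(x, y, z)` in 0-based voxel units (physical
units only on an explicit spacing flag), and marks the root type 1, all
other nodes type 2.

### Blockwise tracing of large volumes

Large volumes are tiled into cubes (default edge 512) overlapping by 15
voxels, traced independently, and assembled.  The assembly rule is
proximity-based: trees from different blocks merge when one has a node
within `merge_tol` (default 2 voxels) of the other's polyline.  The absorbed
tree's nodes within `merge_tol` of the kept polyline are deleted (the
duplicated overlap skeleton), and each surviving fragment is re-rooted at
its node closest to the kept tree and attached there — re-rooting at the
closest node rather than the fragment's original root is what keeps the
assembled geodesic length faithful (no long detour edges).  Stitching does
not re-run the bridging rule across seams; it merges by geometry only.

## The synthetic phantom generator

The generator emulates the input the tracer is designed for — a CNN-style
probability map — together with exact ground truth:

* **Geometry**: unit-step random-walk centerlines whose heading turns at
  most 60° per 10 voxels of arc, with optional ~45° Y-branches per 10-voxel
  segment; walls repel the heading within the same turning budget (a walk
  stops early rather than kink).  Distinct trees are rejection-sampled to
  keep centerlines at least `r_i + r_j + 8` voxels apart so components stay
  disjoint and every bridging decision has a unique right answer.  Tubes are
  rasterized at radius 2–4 voxels (ball-stamping at ≤1-voxel arc spacing).
* **Probability**: foreground `clip(0.9 + N(0, 0.03), 0, 1)`; background
  half-normal `|N(0, 0.03)|` with its tail clamped at 2 standard deviations.
  The clamp encodes a real property of CNN outputs — background is
  *confidently* low, without isolated super-threshold speckles — and it
  guarantees (clamp ≈ 2.0σ < μ_bg + 3σ_bg ≈ 2.45σ of the clamped population)
  that no pure-background voxel crosses the segmentation threshold and that
  a gap filled with the background model always breaks the initial
  segmentation, so bridging, not thresholding, is what gets tested.  The
  clamp shifts the half-normal mean by only ≈ −2%.
* **Gaps**: a gap of length `g` removes the interior centerline samples of an
  open arc interval of length `g`, leaving the surviving fragment voxels `g`
  apart — "gap length" equals the unsupported span the tracer must bridge.
  Gaps are placed ≥ 5 voxels from tips and forks, mutually disjoint.  Gap
  voxels (voxels whose nearest centerline sample is a gap sample) get either
  the background model (a fully failed prediction) or a constant dim plateau
  `gap_level` (a weak but present prediction — the case the corridor term
  exploits).
* **Determinism**: one seeded RNG stream per phantom; identical spec ⇒
  byte-identical volumes.

What the phantoms do *not* model: point-spread anisotropy, somata, crossing
or touching neurites, structured false-positive clutter, and intensity that
varies along a neurite.  Passing the phantom benchmark therefore shows the
tracer is correct *given* a well-behaved probability map; it does not certify
performance on real predictions whose failure modes include merged crossing
fibres (explicitly out of scope) and blob-like false positives.

## Evaluation protocol

Skeletons (traced and gold) are decomposed into maximal unbranched segments
and resampled by arc length to 1-voxel spacing (junctions retained, the last
step of a segment may be shorter).  A traced point is a true positive when
its nearest gold point is strictly within the tolerance (default 6 voxels);
precision is the TP fraction of traced points, recall the matched fraction of
gold points — the two sides use their own denominators, so precision and
recall are each consistent with their own match count.  Morphometrics are
the summed Euclidean edge length (× spacing) and the count of nodes with
degree > 2.

## Numerical choices and degenerate inputs

* Line rasterization samples the segment at its Chebyshev length's worth of
  evenly spaced points and rounds with `floor(x + 0.5)`; the sample points of
  `a → b` and `b → a` coincide, so the chain is symmetric, 26-connected and
  monotone by construction.
* The hybrid segmentation loss (Dice plus foreground-weighted cross-entropy,
  weight 0.5, Dice smoothing ε = 1e-5) clips probabilities to `[1e-7, 1]`
  before the log, so it is finite everywhere.  The Dice denominator uses the
  `+1` stabilizer; `+ε` there would be the natural alternative and differs
  only at third-decimal scale on tiny inputs.
* `low_threshold` reads "exclude at least half the background" as the 50th
  percentile (non-strict ≤) of the sub-0.5 population, capped at 0.1.
* Probability volumes are written as 32-bit floats (round trip exact at that
  precision); masks/labels as integers, labels at ≥ 32 bits.
* Empty traced or gold point sets make precision/recall undefined; the
  report flags them and reports 0 rather than raising.

## Problem sizes used in tests and the acceptance script

The shipped benchmark uses ten 128³ phantoms with two trees each (radii 2–4,
three gaps of 3–6 voxels per tree) and straight radius-3, length-100 tubes
for the centerline, bridging-bound and stitching checks.  These sizes were
chosen to exercise every code path — branching, bridging on both sides of
the feasibility bound, pruning, stitching — at desk scale; the tracer itself
is resolution-independent and the blockwise driver handles volumes larger
than memory-friendly single blocks.

## Known limitations

* Crossing or touching neurites are traced as one object (single-component
  assumption of the connectivity term); disentangling them is a separate
  problem.
* Bridging considers only the straight corridor between the closest voxel
  pair; it does not check directional consistency with the incoming trace,
  so a fragment end lying within `d_t` of an unrelated fragment with a
  noise-level corridor can over-connect.
* The node radius estimate (distance transform at the node center) reflects
  the thresholded mask, not the underlying intensity, and is floored at 1
  voxel.
* Stitching merges by proximity only; a genuine gap that happens to span a
  block seam is not bridged.
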