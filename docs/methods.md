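# Methods

## The topological morphology descriptor

A traced cell is a tree *T* rooted at its soma, with node positions in µm.
The filtration function is the radial distance *f(v) = ‖v − root‖*. The
persistence barcode of *T* under *f* is computed by the elder rule on the
tree's merge structure: processing nodes in post-order, each leaf starts a
component carrying its own *f* value; at a branch point the child component
with the largest maximal *f* survives (ties broken by the smaller carrier
node id, which makes runs deterministic but never changes bar values, since
tied components die at identical coordinates), and every other child
component emits a bar `(its maximal f, f(branch point))`. Multifurcations
are treated as simultaneous pairwise merges: all non-maximal children die
at the branch point's value. Each stem's last surviving component merges at
the soma (`merge = 0`), so the number of zero-merge bars equals the number
of primary processes, and the total bar count equals the leaf count.

Assigning deaths at branch points is exact whenever *f* is non-decreasing
along root-to-leaf paths — true for the synthetic generator by construction
and an excellent approximation for outward-growing cells. For strongly
re-entrant processes the merge radius of a bar is the branch-point value
rather than the path minimum; the test suite checks equivalence with an
independent union–find threshold sweep on monotone trees.

Single-node trees yield an empty barcode with a warning. The barcode is
invariant under rotations about the root and rigid translations; the test
suite verifies this to 1e−9 µm.

### Bar filters

`filter_barcode` selects bars by (a) minimal endpoint ≤ a threshold —
with threshold 0 µm these are the primary processes born at the soma; a
tolerance of 0.5 µm is recommended for traced data whose starting points
rarely sit exactly at the soma centre — and/or (b) bar length ≤ a
threshold (default use case 10 µm, the short terminal processes). The two
criteria compose by conjunction.

## Persistence images

Diagram points (one per bar, coordinates `(origin, merge)` in µm) are
convolved with an isotropic Gaussian and evaluated at the pixel centres of
a shared square grid `[0, (1+padding)·max endpoint]²` (default padding 0.1,
resolution 100×100). The kernel is separable, so each image is assembled as
an outer product of per-axis kernel matrices. Images are normalized to unit
pixel sum, which makes images of different pool sizes comparable and lets a
subtraction image read as over/under-representation; an empty diagram gives
an all-zero image flagged as empty.

Bandwidth: fixed in µm, or `"auto"` = Scott's rule for 2D data
(`n^(−1/6)` times the mean per-axis SD of the pooled points) floored at one
pixel width so single points stay visible. Resolution, padding, bounds and
bandwidth are recorded in every artifact sidecar; pixel-wise operations
refuse images whose grids differ, there is no silent resampling.

The condition-level average image pools all bars of the condition into one
diagram before convolution (the default); a pixel-wise mean of individual
images is available as a flagged variant and is qualitatively similar. The
pixel-wise standard-deviation map uses the population convention
(divisor *m*). The representative image of a collection is the member with
the smallest TMD (L1) distance to the pixel-wise mean, ties to the lowest
index.

## Bootstrapping

From a condition's starting population of *n* cells, one draw picks
`bootstrap_size` = *x* **unique** cells (without replacement within the
draw); draws are repeated `n_samples` = *m* times independently, so the
same subset may recur across draws. Pooled bars of a draw give a
bootstrapped persistence image or a bootstrapped stable rank; feature
vectors and Sholl curves are averaged element-/radius-wise instead. Default
draw counts per condition ship as presets (500, 300, 200 and 2000 for
different analysis scales); the default bootstrap size is 30.

Per-condition RNG streams are derived from the master seed and a CRC of
the condition name: adding or removing a condition never perturbs the
draws of another, and identical (population, spec) inputs reproduce the
sample byte-for-byte in exports.

As *x* grows toward *n* the bootstrapped images converge to the condition
average (exactly equal at *x = n*); the acceptance protocol measures the
median TMD distance to the average over *x* ∈ {2, 5, 10, 20, 40} on a
40-cell population.

## Stable ranks and the kernel SVM

The standard stable rank of a barcode *X* is
*r(t) = #{bars of X with length ≥ t}* — non-increasing, equal to the bar
count at 0, zero beyond the longest bar. A non-negative piecewise-constant
density over the filtration scale generalizes this: each bar's length is
replaced by the density mass over its interval before counting; the
constant-1 density recovers the standard rank. Perturbing every endpoint by
≤ ε moves the rank by ≤ 2ε·(bar count) in L1 — the continuity that makes
these summaries stable.

The kernel *K(X, Y) = ∫₀^∞ r_X(t) r_Y(t) dt* is evaluated exactly: both
step functions are constant between consecutive merged breakpoints, so the
integral is a finite sum (never quadrature). *K* is an L² inner product,
hence Gram matrices are symmetric positive semidefinite (checked to an
eigenvalue tolerance of −1e−8).

The classification protocol is pairwise: 200 bootstrapped standard stable
ranks per condition, a random 240/160 train/validation split, an SVM with
the precomputed Gram matrix and solver defaults otherwise, and the mean
accuracy over 10 repeated splits. The chance-level control assigns both
class labels to bootstraps of one and the same population, making the
labels exchangeable. (Two *independent* populations generated from
identical parameters are not a null: bootstrap draws concentrate around
each finite population's own mean, and the classifier can reach perfect
accuracy on that sampling difference. This is a property of bootstrapping
finite samples, not of the kernel.)

## Embedding, clustering, trajectories

The distance-first route: pairwise TMD distances between bootstrap items →
column-centred SVD of the distance matrix (centring is switchable; the
uncentred first component degenerates to row sums) → the leading
`n_pcs` principal-component scores (default 7, where the singular-value
elbow sits; a 10-PC preset is also named) → UMAP (`n_neighbors=50,
min_dist=1.0, spread=3.0`) or t-SNE (`perplexity=50`). Component signs are
fixed by making each component's largest-magnitude loading positive.
Embedding coordinates are reproducible per seed; their absolute positions
carry no meaning, only relative cluster structure does. Condition-average
images are compared by average-linkage hierarchical clustering under the
TMD distance (scipy linkage).

Trajectory inference is a stage contract around external single-cell
machinery: 100 PCs of the images themselves (not of the distance matrix),
scanpy diffusion maps (10 components, knn 20) on those PCs, then a spring
layout of the kNN graph built in diffusion space (eigenvectors scaled by
their eigenvalues, the constant steady-state component dropped). The
default layout is igraph's Kamada–Kawai stress layout, which keeps weakly
connected condition clusters apart; classic Fruchterman–Reingold is
available but smears near-disconnected cluster graphs. If scanpy or
python-igraph are missing the stage raises a capability error and the rest
of the pipeline remains usable.

## Reference atlas

Given a reference bootstrap sample spanning the known conditions and its
2D trajectory coordinates: coordinates are min–max rescaled to (0, 1) per
axis (bounds stored, so novel conditions may map outside the unit square —
values are never clipped); the 500 most variable pixels across all
reference images, pooled over conditions, are selected (ties to the lower
pixel index; fewer pixels than 500 ⇒ all are used with a warning); and one
least-squares regression per axis (with intercept, switchable) maps the
hv-pixel vector to the rescaled coordinate. Smoothed unit-sum images are
highly collinear, so the design is typically rank-deficient; `lstsq`
resolves this to the minimal-norm solution and the rank deficiency is
logged. A novel condition's bootstrapped images are filtered to the stored
pixels and pushed through both regressors; the result is reported as
per-image positions, their centroid and per-axis SD.

## Synthetic data

The generator is a biased Galton–Watson growth process: `n_stems` primary
processes leave the soma at the origin; each tip extends a segment of
length ~ Normal(mean, sd) truncated positive, in a direction mixing the
previous direction with the outward radial direction (`radial_drift`
weight; any positive drift under the default mixing keeps radial distance
strictly increasing along paths, enabling closed-form barcode checks), and
bifurcates with probability `branch_prob` until `max_depth` generations.
Expected leaf counts follow the recursion L(max_depth)=1,
L(d) = (1−p) + 2p·L(d+1), which the tests use as an oracle.

Stock two-condition presets (A: depth 6, 6 µm segments; B: depth 4, 11 µm
segments; both 4 stems, p=0.45, drift 0.7) emulate ramified cells of
~40–55 µm radial extent differing in branching density — the separable
pair for recovery tests. A four-condition "spectrum" preset family (depth
4→7 against segment length 11→5.5 µm) stands in for a multi-condition
atlas. What the generator does **not** emulate: tracing noise and artifacts,
soma contours, process thickness/volume effects, re-entrant (inward-curving)
processes, within-animal correlations, or condition differences that leave
branch statistics unchanged. Passing recovery tests therefore show the
pipeline's machinery is sound, not that any particular biological contrast
is detectable.

## Validation scales and numerical choices

The acceptance protocol runs at desk scale, chosen once: 200 random trees
(≤ 64 leaves) for oracle equivalence; 15 trees × 20 rigid motions for
invariance; populations of 100 cells/condition with bootstrap size 30 and
200 draws for the embedding recovery; bootstrap size 50 and 200 draws per
class for the SVM protocol; a 4 × 60-cell atlas with 500 reference draws
and 100 query draws per condition at 100×100 resolution. Seeds fix every
random choice; reruns are byte-identical.

Degenerate inputs are defined rather than rejected wherever a definition
exists: empty barcodes give zero images and identically-zero stable ranks,
`K(X, ∅) = 0`, single-member collections are their own average and
representative. Grid mismatches, oversized bootstrap draws (named per
condition), unequal SVM classes and missing upstream CLI artifacts (named
per producing subcommand) raise errors.

## Known limitations

- Only the radial-distance filtration is implemented (no path-distance or
  higher-dimensional persistence), and diagram-space metrics
  (Wasserstein/bottleneck) are out of scope; images are compared in L1.
- Branch-point merge assignment is exact only for monotone-outward growth
  (above).
- The 27-feature extended morphometric panel of legacy pipelines is
  represented by an extensible registry with six implemented features;
  the bootstrapped-feature machinery accepts any registered set.
- Trajectory coordinates depend on the chosen graph layout; only the
  cluster-level geometry (which conditions are adjacent) is meaningful.
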