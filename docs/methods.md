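# Methods

## Model and procedure

The package treats a binned single-cell Hi-C contact map as a recurrence
plot: a symmetric binary relation over chromosome segments that records
which pairs were spatially close when the cell was fixed.  Reconstruction
inverts that relation.  Segments are allele-resolved — node identity is
`(chromosome, allele, bin, resolution)` — and only contacts whose **both**
legs carry an allele label enter the reconstruction.  The only structural
assumption is chain continuity: consecutive segments of the same allele
are declared neighbors (the backbone).  In particular the method assumes
nothing about allele separation or allele shape similarity, which is what
allows the half-phased and unphased contacts to act as genuinely held-out
validation data.

Pipeline, per cell:

1. bin phased contacts at the coarse resolution (default 1 Mb); duplicate
   pairs collapse, intra-bin contacts are dropped (they carry no
   inter-segment information) but counted in diagnostics;
2. add backbone edges over each allele's observed bin range `0..max`;
3. weight every edge `(i, j)` with the Jaccard distance of the
   backbone-augmented neighbor sets,
   `d = |N(i) △ N(j)| / |N(i) ∪ N(j)|`;
4. all-pairs shortest paths through the weighted graph give global
   distances;
5. classical (Torgerson) MDS of the global distance matrix gives 3D
   coordinates;
6. optionally, refine to a finer resolution (default 100 kb) by the
   analogue-neighbor scheme described below.

## Design choices at genuinely open points

**Self in the neighbor set.**  `N(k)` includes `k` itself.  Without this,
two backbone-adjacent nodes with no other contacts would have disjoint
neighbor sets and local distance 1; with it they share two members and
stay properly closer than unrelated nodes.  The convention is switchable
(`include_self=False`) since either reading of "the neighbors at their
corresponding rows" is defensible; coordinates change only slightly.

**Deterministic MDS.**  Classical MDS (double-center, `numpy.linalg.eigh`,
top-3 nonnegative eigenpairs, coordinates `v√λ`) rather than iterative
stress majorization: the eigendecomposition is deterministic, exact on
Euclidean input, and testable to machine precision.  Each eigenvector's
sign is fixed by making its largest-magnitude entry positive, so repeated
runs are byte-identical.  The eigenvalue report records retained and
discarded (negative) mass; geodesic matrices are generally non-Euclidean,
so some negative mass is expected and harmless.

**Zero-weight edges.**  Local distance 0 between nodes with identical
neighbor sets is legitimate.  Shortest paths are computed from a dense
adjacency converted with `csgraph_from_dense(null_value=inf)` so that such
edges survive (a plain sparse matrix would silently drop stored zeros).
Dijkstra from every node; a dense Floyd–Warshall is used only as a test
oracle.

**Disconnected graphs** are a hard error listing component sizes — a
biologically meaningful failure (chromosome pieces with no phased contact
linking them) — with an explicit `largest_component=True` fallback.

**Refinement.**  For each fine segment, its backbone-augmented fine
neighbors are mapped into coarse bins to form a profile; coarse candidates
are ranked by Jaccard distance between that profile and their own neighbor
set in the coarsened map (coarsening the same fine map keeps the two
levels mutually consistent); the best `k = 4` coarse coordinates are
averaged with weights `w_i ∝ 1/(d_i + ε)`, `ε = 1e−6`, normalized to sum
to one — so an exact profile match dominates in the `ε → 0` limit, and the
refined point always lies in the convex hull of its analogues.
Exponential weights `exp(−d_i/d_1)` and an overlap-count similarity are
available as options.  Ties are broken by `(chrom, allele, bin)` order,
keeping runs deterministic.  Fine segments with an empty profile (possible
only for single-bin chains) are linearly interpolated along their allele's
backbone and flagged `interpolated` in the output.

**3D correlation coefficient.**  The embedding is aligned onto the truth
with the optimal similarity transform — translation, rotation, isotropic
scale, reflection permitted (MDS chirality is arbitrary) — and the Pearson
correlation of the stacked per-axis-centered coordinates is returned.
Per-axis centering makes the value exactly invariant to translations of
either argument; it agrees with an independent Procrustes implementation
to ~1e−12.

**Correlation dimension.**  Grassberger–Procaccia: `C(r)` = fraction of
point pairs within `r`, `D2` = least-squares slope of `log C` vs `log r`
over the scaling window.  The default window is `2e−4 ≤ C(r) ≤ 5e−3`,
chosen by calibration on uniform samples of known dimension (line, sphere
surface, solid ball): for bounded point sets the local slope at larger
`C` is biased low by boundary effects — for a uniform ball the *analytic*
slope is already ≈2.86 at `C = 0.01` — while the chosen window recovers
1/2/3 within ±0.1 at n = 2000.  The lower edge is raised automatically to
keep ≥10 pairs in the window, and the window widens upward if it would
contain fewer than five radii; the fitted range is always reported
alongside the estimate.

**Detection limit.**  The constant 22/27 (embedding units) is exposed as a
configurable threshold, used both for consistency scoring and as the
default closeness in the territory ratio.  An optional scale factor
supports comparing reconstructions with different global scales.  The
central-hole radius is operationalized as (minimum radial distance) /
(mean radial distance); a radial-histogram estimator is available behind
`hole_method="histogram"`.

## The synthetic generator

`simulate_polymer` produces per-chromosome maternal/paternal chains as
fixed-step random walks confined to a sphere (default: 1 chromosome × 2
alleles × 500 beads, step 1, nucleus radius 6 — dense enough that
single-digit-percent recurrence rates arise at thresholds of a few step
lengths, the regime the reconstruction is designed for).  A step that
would exit the sphere is redrawn rather than geometrically reflected, so
bond lengths are exactly the step length and confinement is exact — the
two invariants the validation protocol checks.  `derive_contacts` then
emulates the measurement: all non-adjacent bead pairs within the capture
threshold are true contacts (adjacent pairs are excluded — they are
backbone, added deterministically downstream, and would only inflate
consistency); each is detected with probability `q`; each leg keeps its
true allele label with probability `s`, giving the phased/half-phased/
unphased composition `(s², 2s(1−s), (1−s)²)` that mirrors sparse SNV
coverage.  `subsample_points` (every 5th bead by default) emulates coarse
reconstruction over a finer truth; the subsampled structure's resolution
is scaled accordingly.

What the generator does **not** emulate: polymer physics beyond chain
continuity and confinement (no loop extrusion, no compartments, no
nucleolus), Hi-C distance-dependent capture efficiency, genomic coverage
bias in SNV placement, or inter-cell variability.  Passing the recovery
tests therefore shows the *pipeline* inverts distance-threshold contact
maps of connected confined chains faithfully; it does not by itself
certify accuracy on real chromatin.

## Problem sizes and defaults

The validation protocol uses 2 chains × 500 beads (1000 nodes) with the
capture threshold set by quantile to a realized recurrence rate of 7.5%
(the middle of the 5–10% band), full detection and full phasing; shape
recovery is summarized as the minimum 3D correlation over three seeds.
Unit and property tests use 2 × 120-bead polymers.  Default analysis
parameters: 1 Mb coarse, 100 kb fine, `k = 4`, detection limit 22/27, 20
territory shuffles; all randomness flows from explicit integer seeds and
identical configuration yields byte-identical outputs.

## Known limitations

- Global distance matrices are dense (`O(N²)` memory), which bounds the
  resolution at which the *coarse* stage is practical; the refinement
  stage avoids shortest paths and scales linearly in fine segments times
  coarse candidates.
- MDS embeds the single largest metric structure; cells whose phased
  contacts leave the graph disconnected need `largest_component` (losing
  the smaller pieces) or more phased input.
- The legacy no-phasing mode collapses both homologs onto one copy; it
  exists for comparison with predecessor behaviour, not for diploid
  inference.
- Consistency ratios depend on the embedding's overall scale through the
  fixed detection limit; cross-method comparisons should use the provided
  mean-distance rescaling.
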