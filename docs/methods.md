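# Methods

## Conventions

Coordinates are 0-based `(z, y, x)`; all boxes are half-open. Label 0 is
the single ignore value — unsegmented background and voxels erased by
boundary dilation alike — and participates in no metric. Contingency
tables are sparse dictionaries keyed by `(test label, reference label)`,
never dense matrices, because segment ids in real volumes are large and
non-contiguous. All entropies are in bits (log base 2); every probability
is an empirical frequency over the comparison points of one table.

## Comparison domains

A segmentation pair is compared over one of two point sets: every voxel
where both labelings are nonzero, or the synaptic endpoint coordinates
(each connection contributes its pre and its post site as one comparison
point each, weighted equally). The endpoint domain deliberately re-weights
the evaluation toward thin, synapse-bearing processes that occupy a tiny
fraction of the voxel count but carry the connectome. Points where either
label is 0 are excluded from the table and tallied separately as
`ignored`.

## Blockwise computation

The region of interest is tiled by a regular grid (default 64³-voxel
blocks; edge blocks shrink to fit). Contingency tables are built per block
and merged additively — merging is associative and commutative, so any
partition, ordering, or parallel schedule yields the entrywise-identical
table. Segments are first relabeled by connected components within each
block (6-connectivity — faces only, the conservative standard for EM
label volumes), then a global pass unions local components across block
faces when their provenance labels agree. Two consequences are intended:
a body that leaves and re-enters the ROI without a connecting path inside
it is treated as two objects, and per-block VI can treat each subvolume as
an isolated segmentation so that an error is charged to the block that
contains it, not to every block its body passes through. The tests verify
that summary metrics are independent of block shape to 1e-10 and that the
stitched components reproduce unpartitioned connected components exactly.

## Metric details and numerical choices

- **VI.** H(S|G) = Σ_{(s,g)} (n_sg/n)·log2(n_g/n_sg), and symmetrically
  for H(G|S). Computed in double precision from exact integer counts; the
  per-body decomposition is exactly conservative (tested to 1e-10).
- **Per-body scores.** The over score of body g is its share
  P(g)·H(S|G=g) of H(S|G). The under score sums, over test segments s
  touching g, (n_s/n)·H2(n_sg/n_s) with H2 the binary entropy of
  membership in g within s. Both are non-negative by construction.
- **Rand index.** Pair-counting from the table's entries and marginals;
  the adjusted form applies the Hubert–Arabie chance correction and is
  defined as 1.0 in the degenerate single-cluster case where the
  correction's denominator vanishes.
- **Matching.** Reference→test assignment is one-to-one and partial.
  Greedy matching sorts candidate pairs by overlap descending with
  deterministic tie-breaks (smaller test label, then smaller reference
  label); `optimal` uses the Hungarian algorithm on the overlap matrix.
  Matching weights live in the endpoint domain whenever connections are
  supplied — connectivity metrics should be matched on the objects they
  score — and in the voxel domain otherwise.
- **Connectivity correctness.** Connections are matched by identity (the
  same physical synapse), not by edge-weight arithmetic, and edges are
  direction-sensitive (pre→post). Connections with an endpoint on label 0
  are excluded and reported as unresolved. Thresholds are strict (`> k`;
  an `inclusive` flag gives `≥ k`); an empty denominator yields an
  undefined (None) score, never 0. Defaults k ∈ {0, 9}: with the strict
  convention k=9 selects paths of at least 10 synapses.
- **Completeness counts.** Segments are taken largest-first until their
  cumulative size reaches X% of the total; a 1e-9 slack absorbs the
  floating-point boundary when X% of an integer total is itself integral.
- **Boundary dilation.** A nonzero reference voxel is erased iff a voxel
  with a *different* nonzero label lies within Euclidean distance r (in
  voxel units; anisotropy ignored, since the radius is conventionally
  stated in pixels). Implemented exactly as two grey-morphology passes
  with a Euclidean-ball footprint: a voxel is near a different label iff
  the max label within the ball exceeds its own or the min nonzero label
  within the ball is below it. Background adjacency alone never erases.
  Default radius 2; erased-set monotonicity in r is property-tested.
- **Downsampling.** Mode pooling per factor³ block over nonzero labels,
  ties to the smallest label, all-background blocks stay 0; synapse
  coordinates are integer-divided. Axis lengths become ceil(length/f).
- **Orphans.** "Fewer than K" is strict; K defaults to 10 synaptic
  endpoints. Segments with zero endpoints are trivially orphans. For the
  density heat map an orphan is binned by the grid block containing its
  size-weighted centroid.
- **Autapses.** Counted per connection with equal nonzero pre/post labels
  and presented as a ranked outlier list rather than a hard error, since
  genuine biological autapses exist.

## Synthetic scenes

The generator stands in for real groundtruthed volumes at desk scale. It
emulates: dense packing (nearest-seed regions of random seed points fill
the volume; a repair pass keeps each label's largest 6-connected component
and regrows thin digitisation slivers from face-adjacent neighbors, so
every segment is face-connected), synapses straddling segment boundaries
(each connection samples a boundary face, pre on one side, post on the
other, weighted by the inverse size of the smaller segment so thin
processes carry disproportionately many synapses), and three controlled
corruptions: plane splits (each cut keeps both sides connected, so
fragmentation rises by exactly one per cut), false merges of adjacent
pairs (turning former inter-pair connections into exactly that many
autapses), and random boundary shifts. Boundary shifts protect synapse
endpoint voxels and one anchor voxel per segment, so they change voxel
scores while provably preserving segment count and every connection — the
cleanest way to exercise the dilation filter's purpose, at the cost of
not modelling shifts that genuinely break connectivity.

What the scenes do **not** emulate: realistic neuron morphology (segments
are convex blobs, not branching tubes), imaging artifacts, synapse
detection noise, or endpoint placement away from boundaries. In
particular, synthetic endpoints sit exactly on segment boundaries, so any
positive dilation radius erases all of them from the reference; real
synaptic points sit near but not on boundaries. Evaluations that combine
dilation with endpoint metrics are therefore demonstrated on the voxel
domain here. Passing tests show the metrics and the blockwise machinery
are exact and self-consistent, not that any particular segmentation
algorithm scores well on real tissue.

All generator randomness flows from one explicit integer seed per
operation; identical seeds reproduce scenes bit-exactly, and every
corruption is appended to a log from which the expected metric values can
be predicted independently (the perturbation-recovery tests replay this
log against the raw connection list).

## Problem sizes

The test suite works at 16³–64³ for oracle comparisons (brute-force pair
enumeration is quadratic) and 128³ scenes with 100 segments and 1000
connections, over 10 seeds, for perturbation recovery; the acceptance
script uses one 128³ scene corrupted with 10 splits and 2 merges. These
sizes exercise every code path, including multi-block grids, while
keeping a full run on a single core in the low minutes.

## Known limitations

- The whole pipeline is in-process; the mergeable-table and blockwise-CC
  contracts are the seam where a distributed backend would attach, but
  none is provided.
- Skeleton-based metrics (expected run length, warping, tolerant edit
  distance) are out of scope.
- Per-body statistics are keyed by post-connected-components labels;
  provenance to the original ids is reported, but a body disconnected
  within the ROI is scored as several bodies by design.
- `rand_index` needs at least two comparison points and VI at least one;
  empty overlap raises rather than returning a sentinel.
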