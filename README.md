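# conneval

Evaluation of electron-microscopy (EM) connectomics segmentations.

Automatic neuron segmentation of EM volumes is judged, in the end, by the
connectome it produces — yet the widely used voxel-level scores say nothing
about whether synaptic connections between neurons survive the
segmentation. `conneval` scores a test segmentation *S* against a reference
*G* (or against itself, when no reference exists) with both the classical
topological metrics and synapse-aware connectivity metrics, and decomposes
every score to the level where errors can actually be found: per neuron
body and per subvolume.

## Metrics

**Variation of information** (bits, base 2), split into an
over-segmentation and an under-segmentation component:

    VI(S, G) = H(S|G) + H(G|S)

Both conditional entropies are computed from a sparse contingency table of
comparison points — either all voxels where both labelings are nonzero, or
the synaptic endpoint coordinates, which weight exactly the places that
matter for connectivity. H(S|G) decomposes as a sum of non-negative
per-body terms P(g)·H(S|G=g), so the worst-segmented neurons can be
ranked; the **Rand index** (plain and chance-adjusted) is computed from
the same table.

**Connectivity correctness (CC)** resolves each synaptic connection to an
ordered (pre-segment, post-segment) edge under both labelings, matches
reference bodies one-to-one to test segments by greatest overlap (greedy or
Hungarian), and reports the fraction of reference connections whose same
physical synapse also links the matched test segments:

    CC(S|G) = Σ_(gi,gj) |x(A(gi), A(gj)) ∩ x(gi, gj)| / Σ_(gi,gj) |x(gi, gj)|

where x(a, b) is the set of connections between two segments and A the
one-to-one assignment. A thresholded variant (recCC_k / preCC_k) counts
only connection paths stronger than k synapses, as recall over reference
pairs and precision over test pairs.

**Fragmentation** Frag = |S| − |G| lower-bounds the merge edits needed to
repair an over-segmentation, and its thresholded variant counts the
segments needed for an X%-complete connectome. Without any reference,
**orphan counts** (segments with fewer than K synaptic endpoints) and
**autapse counts** (connections of a segment onto itself, a false-merge
signal) screen a segmentation directly.

Large volumes are handled blockwise: all tables merge additively across
grid blocks, segments are relabeled by local-then-global connected
components (so bodies merged only outside the region of interest stay
separate), and every summary number is independent of the block shape.
Preparation filters include reference boundary dilation (erasing voxels
within a Euclidean radius of an inter-segment boundary, so boundary-shift
noise does not dominate), sparse-evaluation masking, small-orphan removal,
and mode-pooled label downsampling.

## Worked example

Generate a toy connectome (64³ voxels, 50 segments, 500 synapses), corrupt
it with five plane splits, and evaluate:

```python
import conneval as cv

scene = cv.generate_scene((64, 64, 64), 50, 500, seed=11)
cv.corrupt_split(scene, 5, seed=12)
report = cv.run_evaluation(cv.EvaluationConfig(
    test=scene.current, groundtruth=scene.ground_truth,
    synapses=scene.connections, dilation_radius=0, block_shape=(32, 32, 32),
))
vox, syn = report.summary["voxels"], report.summary["synapse_endpoints"]
print("vox vi_split %.4f vi_merge %.4f rand %.4f frag %d"
      % (vox["vi_split"], vox["vi_merge"], vox["rand"], vox["frag"]))
print("syn cc %.4f reccc0 %.4f preccc0 %.4f"
      % (syn["cc"], syn["reccc_0"], syn["preccc_0"]))
```

prints

```
vox vi_split 0.0528 vi_merge 0.0000 rand 0.9994 frag 5
syn cc 0.9580 reccc0 0.9713 preccc0 0.9331
```

All five splits are recovered in the fragmentation count; the VI error is
purely an over-segmentation (split) component; about 4% of synaptic
connections are lost because some synapses land on split-off fragments
that the one-to-one assignment cannot cover. The report also ranks bodies:
here the worst body kept only 58% of its connections
(`report.bodies["worst"][0]`).

The same pipeline runs from the shell:

```sh
conneval synthesize --shape 64,64,64 --segments 50 --connections 500 \
    --corrupt split:5 --seed 11 --out-prefix /tmp/scene
conneval evaluate --test /tmp/scene_test.h5 --groundtruth /tmp/scene_groundtruth.h5 \
    --synapses /tmp/scene_synapses.json --dilation-radius 0 --out report.json
conneval compare report.json other_report.json
```

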