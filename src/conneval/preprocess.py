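"""Restructuring filters applied before metric computation.

These implement the evaluation pipeline's preparation stages: partitioning
the region of interest into a regular block grid, relabeling segments into
face-connected components locally per block and stitching them back
globally, erasing ground-truth voxels near inter-segment boundaries,
restricting to the traced (sparsely ground-truthed) subset, removing tiny
ground-truth fragments, and mode-pooled label downsampling.

Connected-component analysis uses 6-connectivity (faces only) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.cluster.hierarchy import DisjointSet
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _csgraph_cc

from .core import GridSpec, LabelVolume

__all__ = [
    "ComponentRelabeling",
    "partition_grid",
    "extract_block",
    "local_connected_components",
    "global_connected_components",
    "apply_relabeling",
    "dilate_gt_boundaries",
    "filter_sparse_bodies",
    "filter_small_orphans_gt",
    "downsample_labels",
]


@dataclass
class ComponentRelabeling:
    """Injective relabeling produced by connected-component analysis.

    ``provenance`` traces every new label back to the original segment id it
    was carved from; ``mapping`` sends intermediate labels to final ones
    (identity when absent).
    """

    provenance: dict[int, int] = field(default_factory=dict)
    mapping: dict[int, int] = field(default_factory=dict)

    def final(self, label: int) -> int:
        return self.mapping.get(label, label)

    def original(self, label: int) -> int:
        return self.provenance.get(label, label)

    def compose(self, later: "ComponentRelabeling") -> "ComponentRelabeling":
        """Apply ``self`` first, then ``later``."""
        mapping = {k: later.final(v) for k, v in self.mapping.items()}
        for k, v in later.mapping.items():
            mapping.setdefault(k, v)
        provenance = dict(later.provenance)
        for new, orig in self.provenance.items():
            provenance[later.final(new)] = orig
        return ComponentRelabeling(provenance=provenance, mapping=mapping)


def partition_grid(
    bounds: tuple[Sequence[int], Sequence[int]], block_shape: Sequence[int]
) -> GridSpec:
    """Tile a half-open bounding box with a regular grid of blocks.

    Edge blocks may extend past ``bounds``; consumers clip them.  Every
    block index in the returned grid belongs to the ROI.
    """
    start, stop = (tuple(int(c) for c in b) for b in bounds)
    if any(b <= a for a, b in zip(start, stop)):
        raise ValueError(f"empty bounds {start}..{stop}")
    bs = tuple(int(b) for b in block_shape)
    if any(b <= 0 for b in bs):
        raise ValueError(f"block_shape must be positive, got {bs}")
    counts = [-(-(b - a) // s) for a, b, s in zip(start, stop, bs)]
    blocks = frozenset(
        (i, j, k) for i in range(counts[0]) for j in range(counts[1]) for k in range(counts[2])
    )
    return GridSpec(block_shape=bs, roi_blocks=blocks, origin=start)


def extract_block(volume: LabelVolume, grid: GridSpec, index: Sequence[int]) -> LabelVolume:
    """Clip one grid block out of a volume (edge blocks shrink to fit)."""
    bstart, bstop = grid.block_bounds(index)
    vstart, vstop = volume.bounds
    lo = tuple(max(a, b) for a, b in zip(bstart, vstart))
    hi = tuple(min(a, b) for a, b in zip(bstop, vstop))
    if any(h <= l for l, h in zip(lo, hi)):
        raise ValueError(f"block {tuple(index)} does not intersect the volume")
    sl = tuple(slice(l - o, h - o) for l, h, o in zip(lo, hi, volume.offset))
    return LabelVolume(volume.data[sl], offset=lo, resolution=volume.resolution)


def _equal_label_components(data: np.ndarray) -> tuple[np.ndarray, int]:
    """Component index per voxel under face adjacency of equal nonzero labels.

    Returns ``(comp, n_comp)`` where background voxels carry component -1.
    """
    n = data.size
    shape = data.shape
    flat_index = np.arange(n).reshape(shape)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    for axis in range(3):
        if shape[axis] < 2:
            continue
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        a, b = data[tuple(lo)], data[tuple(hi)]
        same = (a == b) & (a != 0)
        rows.append(flat_index[tuple(lo)][same])
        cols.append(flat_index[tuple(hi)][same])
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
    else:
        r = c = np.empty(0, dtype=np.intp)
    graph = coo_matrix((np.ones(len(r), dtype=np.int8), (r, c)), shape=(n, n))
    _, comp = _csgraph_cc(graph, directed=False)
    comp = comp.reshape(shape)
    nz = data != 0
    comp = np.where(nz, comp, -1)
    n_comp = int(comp.max()) + 1 if nz.any() else 0
    return comp, n_comp


def local_connected_components(
    volume: LabelVolume, start_label: int = 1
) -> tuple[LabelVolume, ComponentRelabeling]:
    """Split every segment into its maximal 6-connected pieces.

    Each piece receives a fresh label (consecutive from ``start_label``,
    ordered by original label then first-voxel position, so the result is
    deterministic); provenance records the original segment id.
    """
    data = volume.data
    comp, _ = _equal_label_components(data)
    nz = data != 0
    if not nz.any():
        return volume.with_data(np.zeros_like(data)), ComponentRelabeling()

    comp_nz = comp[nz]
    lab_nz = data[nz]
    flat_pos = np.flatnonzero(nz.ravel())
    # one row per component: (original label, first voxel) for deterministic order
    order = np.lexsort((flat_pos, comp_nz))
    comp_sorted = comp_nz[order]
    first = np.concatenate(([True], comp_sorted[1:] != comp_sorted[:-1]))
    comp_ids = comp_sorted[first]
    comp_orig = lab_nz[order][first]
    comp_first_pos = flat_pos[order][first]
    rank = np.lexsort((comp_first_pos, comp_orig))
    new_of_comp = np.empty(len(comp_ids), dtype=np.int64)
    new_of_comp[rank] = np.arange(start_label, start_label + len(comp_ids))

    lut = np.empty(int(comp.max()) + 1, dtype=np.int64)
    lut[comp_ids] = new_of_comp
    out = np.zeros(data.shape, dtype=np.int64)
    out[nz] = lut[comp[nz]]
    provenance = {
        int(new): int(orig) for new, orig in zip(new_of_comp, comp_orig)
    }
    return volume.with_data(out), ComponentRelabeling(provenance=provenance)


def global_connected_components(
    blocks: list[tuple[tuple[int, int, int], LabelVolume, ComponentRelabeling]],
    grid: GridSpec,
) -> ComponentRelabeling:
    """Stitch per-block local components across block faces.

    Two local components receive the same final label iff they share an
    original segment id and a chain of face-adjacent voxel pairs with equal
    provenance connects them through the ROI.  Components of one original
    segment connected only outside the ROI stay distinct.  Final labels are
    the smallest member label of each merged family, keeping them unique.
    """
    by_index = {tuple(i): (v, r) for i, v, r in blocks}
    all_labels: set[int] = set()
    provenance: dict[int, int] = {}
    for _, (vol, rel) in by_index.items():
        labs = vol.labels()
        for lab in labs:
            lab = int(lab)
            if lab in all_labels:
                raise ValueError(
                    f"local label {lab} appears in more than one block; "
                    "local relabelings must use disjoint ranges"
                )
            all_labels.add(lab)
        for lab, orig in rel.provenance.items():
            provenance[int(lab)] = int(orig)

    ds = DisjointSet(sorted(all_labels))
    for index in sorted(by_index):
        vol_a, rel_a = by_index[index]
        for axis in range(3):
            nbr = list(index)
            nbr[axis] += 1
            nbr = tuple(nbr)
            if nbr not in by_index:
                continue
            vol_b, rel_b = by_index[nbr]
            face_a, face_b = _touching_faces(vol_a, vol_b, axis)
            if face_a is None:
                continue
            a = face_a.ravel()
            b = face_b.ravel()
            both = (a != 0) & (b != 0)
            pairs = np.unique(np.stack([a[both], b[both]], axis=1), axis=0)
            for la, lb in pairs:
                la, lb = int(la), int(lb)
                if rel_a.original(la) == rel_b.original(lb):
                    ds.merge(la, lb)

    mapping: dict[int, int] = {}
    for subset in ds.subsets():
        final = min(subset)
        for lab in subset:
            if lab != final:
                mapping[int(lab)] = int(final)
    return ComponentRelabeling(provenance=provenance, mapping=mapping)


def _touching_faces(
    a: LabelVolume, b: LabelVolume, axis: int
) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Overlapping boundary faces where block b starts right after block a."""
    a_start, a_stop = a.bounds
    b_start, b_stop = b.bounds
    if a_stop[axis] != b_start[axis]:
        return None, None
    lo = [max(sa, sb) for sa, sb in zip(a_start, b_start)]
    hi = [min(ea, eb) for ea, eb in zip(a_stop, b_stop)]
    lo[axis], hi[axis] = a_stop[axis] - 1, a_stop[axis]
    if any(h <= l for l, h in zip(lo, hi)):
        return None, None
    sl_a = tuple(slice(l - o, h - o) for l, h, o in zip(lo, hi, a.offset))
    lo[axis], hi[axis] = b_start[axis], b_start[axis] + 1
    sl_b = tuple(slice(l - o, h - o) for l, h, o in zip(lo, hi, b.offset))
    return a.data[sl_a], b.data[sl_b]


def apply_relabeling(volume: LabelVolume, relabeling: ComponentRelabeling) -> LabelVolume:
    """Map every label through ``relabeling.final``; unmapped labels pass through."""
    if not relabeling.mapping:
        return volume
    data = volume.data
    uniq = np.unique(data)
    lut = np.array([relabeling.final(int(u)) for u in uniq], dtype=np.int64)
    idx = np.searchsorted(uniq, data)
    return volume.with_data(lut[idx])


def _ball_footprint(radius: int) -> np.ndarray:
    r = int(radius)
    zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (zz * zz + yy * yy + xx * xx) <= r * r


def dilate_gt_boundaries(G: LabelVolume, radius: int) -> LabelVolume:
    """Erase ground-truth voxels near boundaries between different segments.

    Every nonzero voxel within Euclidean distance ``radius`` (in voxel
    units) of a voxel carrying a *different* nonzero label is set to 0, so
    that small boundary-placement differences between segmentations do not
    dominate voxel-level scores.  Radius 0 is the identity.
    """
    if radius < 0:
        raise ValueError(f"dilation radius must be non-negative, got {radius}")
    if radius == 0:
        return G
    fp = _ball_footprint(radius)
    data = G.data
    hi = ndi.grey_dilation(data, footprint=fp, mode="reflect")
    sentinel = np.iinfo(np.int64).max
    lo_in = np.where(data == 0, sentinel, data.astype(np.int64))
    lo = ndi.grey_erosion(lo_in, footprint=fp, mode="reflect")
    near_other = (hi > data) | (lo < data)
    out = np.where((data != 0) & near_other, 0, data)
    return G.with_data(out)


def filter_sparse_bodies(S: LabelVolume, G: LabelVolume) -> tuple[LabelVolume, LabelVolume]:
    """Restrict both volumes to the traced subset (where G is nonzero)."""
    if S.data.shape != G.data.shape or S.offset != G.offset:
        raise ValueError("filter_sparse_bodies requires aligned volumes")
    mask = G.data != 0
    return S.with_data(np.where(mask, S.data, 0)), G.with_data(np.where(mask, G.data, 0))


def filter_small_orphans_gt(G: LabelVolume, min_size: int) -> LabelVolume:
    """Relabel ground-truth segments smaller than ``min_size`` voxels to 0."""
    if min_size < 0:
        raise ValueError("min_size must be non-negative")
    if min_size == 0:
        return G
    uniq, cnt = np.unique(G.data, return_counts=True)
    small = set(int(u) for u, c in zip(uniq, cnt) if u != 0 and c < min_size)
    if not small:
        return G
    keep = np.array([0 if int(u) in small else int(u) for u in uniq], dtype=G.data.dtype)
    idx = np.searchsorted(uniq, G.data)
    return G.with_data(keep[idx])


def downsample_labels(volume: LabelVolume, factor: int | Sequence[int]) -> LabelVolume:
    """Mode-pool each ``factor``-sized block to its most frequent nonzero label.

    Ties break to the smallest label; all-background blocks stay 0.  Offset
    is integer-divided and resolution multiplied by the factor, and each
    axis length becomes ``ceil(length / factor)``.
    """
    f = tuple(int(factor) for _ in range(3)) if np.isscalar(factor) else tuple(int(x) for x in factor)
    if any(x < 1 for x in f):
        raise ValueError(f"downsample factor must be >= 1, got {f}")
    if f == (1, 1, 1):
        return volume
    data = vdata = volume.data
    pad = [(0, (-s) % x) for s, x in zip(vdata.shape, f)]
    if any(p[1] for p in pad):
        data = np.pad(vdata, pad, mode="constant", constant_values=0)
    nz_, ny_, nx_ = (s // x for s, x in zip(data.shape, f))
    blocks = (
        data.reshape(nz_, f[0], ny_, f[1], nx_, f[2])
        .transpose(0, 2, 4, 1, 3, 5)
        .reshape(nz_ * ny_ * nx_, f[0] * f[1] * f[2])
    )
    n_blocks, k = blocks.shape
    bid = np.repeat(np.arange(n_blocks), k)
    lab = blocks.ravel()
    keep = lab != 0
    bid, lab = bid[keep], lab[keep]
    out_flat = np.zeros(n_blocks, dtype=np.int64)
    if len(lab):
        rows, cnt = np.unique(np.stack([bid, lab.astype(np.int64)], axis=1), axis=0, return_counts=True)
        order = np.lexsort((rows[:, 1], -cnt, rows[:, 0]))
        rows, cnt = rows[order], cnt[order]
        first = np.concatenate(([True], rows[1:, 0] != rows[:-1, 0]))
        out_flat[rows[first, 0]] = rows[first, 1]
    out = out_flat.reshape(nz_, ny_, nx_)
    offset = tuple(o // x for o, x in zip(volume.offset, f))
    resolution = tuple(r * x for r, x in zip(volume.resolution, f))
    return LabelVolume(out, offset=offset, resolution=resolution)
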