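"""Seeded toy connectomes with known-answer corruptions.

Scenes emulate the inputs of a real evaluation: a densely packed label
volume (nearest-seed regions, so every segment is convex and
face-connected), a list of synaptic connections whose pre and post sites
straddle segment boundaries (sampling is biased toward boundaries of small
segments, mimicking synapses on thin neurites), and a log of corruption
operations.  Because every corruption is recorded with its parameters, the
effect on each metric can be predicted independently and compared against
the evaluator — the basis of the perturbation-recovery tests.

All randomness flows from one explicit integer seed per operation; the
same seed always reproduces the same scene bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .core import LabelVolume, SynapseConnection

__all__ = [
    "SyntheticScene",
    "generate_scene",
    "corrupt_split",
    "corrupt_merge",
    "corrupt_boundary_shift",
]


@dataclass
class SyntheticScene:
    """A generated ground truth plus the evolving corrupted test volume."""

    ground_truth: LabelVolume
    connections: list[SynapseConnection]
    corruption_log: list[dict] = field(default_factory=list)
    seed_points: dict[int, tuple[int, int, int]] = field(default_factory=dict)
    test_volume: LabelVolume | None = None

    @property
    def current(self) -> LabelVolume:
        """Latest corrupted volume (the ground truth if never corrupted)."""
        return self.test_volume if self.test_volume is not None else self.ground_truth

    def endpoint_voxels(self) -> set[tuple[int, int, int]]:
        pts: set[tuple[int, int, int]] = set()
        for c in self.connections:
            pts.add(c.pre)
            pts.add(c.post)
        return pts


def _boundary_faces(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates (N, 3) of face-adjacent voxel pairs with different nonzero labels."""
    sides_a = []
    sides_b = []
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        a, b = data[tuple(lo)], data[tuple(hi)]
        differ = (a != b) & (a != 0) & (b != 0)
        coords = np.argwhere(differ)
        if len(coords):
            ca = coords.copy()
            cb = coords.copy()
            cb[:, axis] += 1
            sides_a.append(ca)
            sides_b.append(cb)
    if not sides_a:
        return np.empty((0, 3), dtype=int), np.empty((0, 3), dtype=int)
    return np.concatenate(sides_a), np.concatenate(sides_b)


def _enforce_face_connectivity(data: np.ndarray) -> np.ndarray:
    """Reassign minor disconnected pieces of each label to adjacent segments.

    Digitised nearest-seed regions are convex in the continuum but thin
    slivers can voxelise into diagonal chains that fall apart under
    6-connectivity.  Each label keeps its largest component; voxels of the
    smaller pieces are regrown, one face step at a time, from whichever
    assigned neighbor carries the largest label — deterministic, and every
    reassigned voxel attaches to its donor by a face, so the result is
    face-connected by construction.
    """
    from .preprocess import _equal_label_components

    comp, _ = _equal_label_components(data)
    nz = data != 0
    if not nz.any():
        return data
    comp_nz = comp[nz]
    lab_nz = data[nz]
    sizes = np.bincount(comp_nz)
    uniq_comp, first = np.unique(comp_nz, return_index=True)
    comp_label = lab_nz[first]
    core: dict[int, int] = {}
    for c, lab in zip(uniq_comp, comp_label):
        c, lab = int(c), int(lab)
        best = core.get(lab)
        if best is None or sizes[c] > sizes[best] or (sizes[c] == sizes[best] and c < best):
            core[lab] = c
    core_set = set(core.values())
    minor = nz & ~np.isin(comp, list(core_set))
    if not minor.any():
        return data
    out = np.where(minor, 0, data)
    while minor.any():
        winner = np.zeros_like(out)
        for axis in range(3):
            for shift in (1, -1):
                neigh = np.roll(out, shift, axis=axis)
                edge = [slice(None)] * 3
                edge[axis] = slice(0, 1) if shift == 1 else slice(-1, None)
                neigh[tuple(edge)] = 0
                winner = np.maximum(winner, neigh)
        grow = minor & (winner != 0)
        if not grow.any():
            raise RuntimeError("disconnected fragment cannot be regrown")
        out[grow] = winner[grow]
        minor &= ~grow
    return out


def generate_scene(
    shape: Sequence[int],
    n_segments: int,
    n_connections: int,
    seed: int,
) -> SyntheticScene:
    """Generate a space-filling toy segmentation with synapse annotations.

    Segments are the nearest-seed (Voronoi) regions of ``n_segments``
    distinct random points, labeled 1..n.  Connections are sampled from
    boundary faces between segments, weighted by the inverse size of the
    smaller segment at the face so thin processes carry proportionally more
    synapses; the pre site sits on one side of the face and the post site on
    the other, so the ground truth has no autapses by construction.
    """
    shape = tuple(int(s) for s in shape)
    if n_segments < 2:
        raise ValueError("need at least 2 segments")
    n_voxels = int(np.prod(shape))
    if n_segments > n_voxels:
        raise ValueError(
            f"cannot host {n_segments} segments in a volume of {n_voxels} voxels"
        )
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_voxels, size=n_segments, replace=False)
    seeds = np.stack(np.unravel_index(flat, shape), axis=1)
    tree = cKDTree(seeds)
    grid = np.stack(
        np.meshgrid(*(np.arange(s) for s in shape), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    _, nearest = tree.query(grid, k=1)
    data = (nearest + 1).astype(np.int64).reshape(shape)
    data = _enforce_face_connectivity(data)
    volume = LabelVolume(data)
    seed_points = {}
    for i in range(n_segments):
        p = tuple(int(c) for c in seeds[i])
        if data[p] != i + 1:  # seed voxel lost during connectivity repair
            p = tuple(int(c) for c in np.argwhere(data == i + 1)[0])
        seed_points[i + 1] = p

    faces_a, faces_b = _boundary_faces(data)
    if n_connections > 0 and len(faces_a) == 0:
        raise ValueError("no segment boundaries available to place connections on")
    connections: list[SynapseConnection] = []
    if n_connections > 0:
        sizes = np.bincount(data.ravel(), minlength=n_segments + 1)
        lab_a = data[faces_a[:, 0], faces_a[:, 1], faces_a[:, 2]]
        lab_b = data[faces_b[:, 0], faces_b[:, 1], faces_b[:, 2]]
        weight = 1.0 / np.minimum(sizes[lab_a], sizes[lab_b])
        weight /= weight.sum()
        chosen = rng.choice(len(faces_a), size=n_connections, replace=True, p=weight)
        flip = rng.random(n_connections) < 0.5
        for i, (fi, fl) in enumerate(zip(chosen, flip)):
            pre, post = faces_a[fi], faces_b[fi]
            if fl:
                pre, post = post, pre
            connections.append(
                SynapseConnection(pre=tuple(pre), post=tuple(post), id=i)
            )
    return SyntheticScene(
        ground_truth=volume, connections=connections, seed_points=seed_points
    )


def _is_connected(mask: np.ndarray) -> bool:
    _, n = ndi.label(mask)
    return n <= 1


def corrupt_split(scene: SyntheticScene, m: int, seed: int) -> LabelVolume:
    """Apply m random plane cuts, each splitting one segment into two.

    Each cut picks a segment and an axis-aligned plane leaving both sides
    nonempty and face-connected; the far side receives a fresh label, so
    the fragmentation count rises by exactly one per cut.  Cuts are recorded
    in the corruption log.
    """
    if m < 0:
        raise ValueError("number of splits must be non-negative")
    rng = np.random.default_rng(seed)
    data = scene.current.data.copy()
    next_label = int(data.max()) + 1
    for _ in range(m):
        cut = _find_plane_cut(data, rng)
        if cut is None:
            raise ValueError("no splittable segment remains")
        label, axis, plane = cut
        coords = np.argwhere(data == label)
        far = coords[coords[:, axis] >= plane]
        data[far[:, 0], far[:, 1], far[:, 2]] = next_label
        scene.corruption_log.append(
            {
                "op": "split",
                "label": int(label),
                "axis": int(axis),
                "plane": int(plane),
                "new_label": int(next_label),
                "seed": int(seed),
            }
        )
        next_label += 1
    out = scene.current.with_data(data)
    scene.test_volume = out
    return out


def _find_plane_cut(
    data: np.ndarray, rng: np.random.Generator, attempts: int = 200
) -> tuple[int, int, int] | None:
    labels = np.unique(data)
    labels = labels[labels != 0]
    for _ in range(attempts):
        label = int(rng.choice(labels))
        coords = np.argwhere(data == label)
        axes = [a for a in range(3) if coords[:, a].min() < coords[:, a].max()]
        if not axes:
            continue
        axis = int(rng.choice(axes))
        lo, hi = int(coords[:, axis].min()), int(coords[:, axis].max())
        plane = int(rng.integers(lo + 1, hi + 1))
        near = coords[coords[:, axis] < plane]
        far = coords[coords[:, axis] >= plane]
        if not (len(near) and len(far)):
            continue
        if _sides_connected(data.shape, near) and _sides_connected(data.shape, far):
            return label, axis, plane
    return None


def _sides_connected(shape: tuple[int, ...], coords: np.ndarray) -> bool:
    lo = coords.min(axis=0)
    hi = coords.max(axis=0) + 1
    mask = np.zeros(tuple(hi - lo), dtype=bool)
    mask[tuple((coords - lo).T)] = True
    return _is_connected(mask)


def corrupt_merge(
    scene: SyntheticScene, pairs: Sequence[tuple[int, int]]
) -> LabelVolume:
    """Relabel each adjacent segment pair to a single label (the smaller one).

    Former connections between the members of a pair become autapses in the
    corrupted volume.  Non-adjacent pairs are rejected.
    """
    data = scene.current.data.copy()
    for a, b in pairs:
        a, b = int(a), int(b)
        if not _are_adjacent(data, a, b):
            raise ValueError(f"segments {a} and {b} are not face-adjacent")
        into = min(a, b)
        other = max(a, b)
        data[data == other] = into
        scene.corruption_log.append(
            {"op": "merge", "a": a, "b": b, "into": into}
        )
    out = scene.current.with_data(data)
    scene.test_volume = out
    return out


def _are_adjacent(data: np.ndarray, a: int, b: int) -> bool:
    if a == b or not ((data == a).any() and (data == b).any()):
        return False
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        x, y = data[tuple(lo)], data[tuple(hi)]
        if (((x == a) & (y == b)) | ((x == b) & (y == a))).any():
            return True
    return False


def corrupt_boundary_shift(scene: SyntheticScene, radius: int, seed: int) -> LabelVolume:
    """Randomly push inter-segment boundaries by up to ``radius`` voxel steps.

    Per iteration, boundary voxels may adopt the label of a face neighbor
    (winner chosen by a per-iteration random label priority).  Voxels hosting
    a synapse endpoint and one anchor voxel per segment are never reassigned,
    so the segment count and every connection's endpoint labels are
    preserved: the corruption changes voxel-level scores without changing
    topology or connectivity.
    """
    if radius < 0:
        raise ValueError("shift radius must be non-negative")
    data = scene.current.data.copy()
    if radius == 0:
        return scene.current
    rng = np.random.default_rng(seed)
    protected = np.zeros(data.shape, dtype=bool)
    for p in scene.endpoint_voxels():
        protected[p] = True
    for lab, p in scene.seed_points.items():
        if data[p] == lab:
            protected[p] = True
    # ensure every label keeps at least one voxel even after earlier corruption
    labels = np.unique(data)
    labels = labels[labels != 0]
    for lab in labels:
        coords = np.argwhere((data == lab) & protected)
        if not len(coords):
            first = np.argwhere(data == lab)[0]
            protected[tuple(first)] = True

    max_label = int(data.max())
    for _ in range(radius):
        prio = np.concatenate(([-1.0], rng.random(max_label)))  # background never wins
        prio_vol = prio[data]
        winner_prio = prio_vol.copy()
        winner_label = data.copy()
        for axis in range(3):
            for shift in (1, -1):
                neigh_prio = np.roll(prio_vol, shift, axis=axis)
                neigh_label = np.roll(data, shift, axis=axis)
                edge = [slice(None)] * 3
                edge[axis] = slice(0, 1) if shift == 1 else slice(-1, None)
                neigh_prio[tuple(edge)] = -1.0
                better = neigh_prio > winner_prio
                winner_prio = np.where(better, neigh_prio, winner_prio)
                winner_label = np.where(better, neigh_label, winner_label)
        flip = rng.random(data.shape) < 0.5
        move = (data != 0) & (winner_label != data) & (winner_label != 0) & flip & ~protected
        data = np.where(move, winner_label, data)

    scene.corruption_log.append({"op": "shift", "radius": int(radius), "seed": int(seed)})
    out = scene.current.with_data(data)
    scene.test_volume = out
    return out
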