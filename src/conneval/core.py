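"""Domain types and contingency-table construction.

Conventions used throughout the package (stated once, here):

* Coordinates are 0-based and ordered ``(z, y, x)``.
* Bounding boxes are half-open: ``[offset, offset + shape)``.
* Label ``0`` is the single ignore value, covering both unsegmented
  background and voxels erased by ground-truth boundary dilation.  It
  participates in no metric.
* Contingency tables are sparse mappings; segment ids may be large and
  non-contiguous, so dense label matrices are never materialised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "LabelVolume",
    "SynapseConnection",
    "ContingencyTable",
    "GridSpec",
    "build_contingency",
    "merge_contingency",
    "label_at",
]

VOXELS = "voxels"
SYNAPSE_ENDPOINTS = "synapse_endpoints"
_DOMAIN_KINDS = (VOXELS, SYNAPSE_ENDPOINTS)


@dataclass(frozen=True)
class LabelVolume:
    """A 3D array of non-negative segment identifiers.

    Parameters
    ----------
    data
        3D integer array of segment ids; 0 means background/ignore.
    offset
        ``(z, y, x)`` voxel coordinate of ``data[0, 0, 0]`` in the
        global frame.
    resolution
        Nanometres per voxel along ``(z, y, x)``.
    """

    data: np.ndarray
    offset: tuple[int, int, int] = (0, 0, 0)
    resolution: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"label volume must be 3D, got shape {data.shape}")
        if not np.issubdtype(data.dtype, np.integer):
            raise ValueError(f"label volume must be integer-typed, got {data.dtype}")
        if data.size and data.min() < 0:
            raise ValueError("segment ids must be non-negative")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "offset", tuple(int(o) for o in self.offset))
        object.__setattr__(self, "resolution", tuple(float(r) for r in self.resolution))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def bounds(self) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
        """Half-open global bounding box ``(start, stop)``."""
        start = self.offset
        stop = tuple(o + s for o, s in zip(self.offset, self.data.shape))
        return start, stop

    def contains(self, p: Sequence[int]) -> bool:
        start, stop = self.bounds
        return all(a <= int(c) < b for c, a, b in zip(p, start, stop))

    def labels(self) -> np.ndarray:
        """Sorted distinct nonzero labels present in the volume."""
        u = np.unique(self.data)
        return u[u != 0]

    def with_data(self, data: np.ndarray) -> "LabelVolume":
        return LabelVolume(data, self.offset, self.resolution)


@dataclass(frozen=True)
class SynapseConnection:
    """One synaptic contact: a presynaptic and a postsynaptic point.

    Coordinates are global-frame ``(z, y, x)`` voxel positions; ``id`` is
    an opaque identifier used for connection-identity matching.
    """

    pre: tuple[int, int, int]
    post: tuple[int, int, int]
    id: object = None

    def __post_init__(self) -> None:
        pre = tuple(int(c) for c in self.pre)
        post = tuple(int(c) for c in self.post)
        if pre == post:
            raise ValueError(f"connection {self.id!r}: pre and post coincide at {pre}")
        object.__setattr__(self, "pre", pre)
        object.__setattr__(self, "post", post)


@dataclass
class ContingencyTable:
    """Sparse joint count of comparison points per (test, reference) label pair.

    ``counts[(s, g)]`` is the number of comparison points (voxels or synapse
    endpoints) carrying test label ``s`` and reference label ``g``, both
    nonzero.  ``ignored`` counts points excluded because either label was 0.
    Tables over the same domain kind merge additively, which is the seam
    that lets every summary metric be computed blockwise.
    """

    counts: dict[tuple[int, int], int] = field(default_factory=dict)
    domain_kind: str = VOXELS
    ignored: int = 0

    def __post_init__(self) -> None:
        if self.domain_kind not in _DOMAIN_KINDS:
            raise ValueError(f"unknown domain_kind {self.domain_kind!r}")
        self.counts = {
            (int(s), int(g)): int(c) for (s, g), c in self.counts.items() if c
        }
        for (s, g), c in self.counts.items():
            if s == 0 or g == 0:
                raise ValueError("contingency table must not contain label 0")
            if c < 0:
                raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def marginal_s(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for (s, _), c in self.counts.items():
            out[s] = out.get(s, 0) + c
        return out

    def marginal_g(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for (_, g), c in self.counts.items():
            out[g] = out.get(g, 0) + c
        return out

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(
            {(g, s): c for (s, g), c in self.counts.items()},
            domain_kind=self.domain_kind,
            ignored=self.ignored,
        )

    def __iter__(self) -> Iterator[tuple[tuple[int, int], int]]:
        return iter(self.counts.items())

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class GridSpec:
    """A regular grid of half-open blocks partitioning a region of interest.

    ``roi_blocks`` holds the ``(bz, by, bx)`` indices of blocks belonging to
    the ROI; block ``(0, 0, 0)`` starts at ``origin``.
    """

    block_shape: tuple[int, int, int]
    roi_blocks: frozenset[tuple[int, int, int]]
    origin: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        bs = tuple(int(b) for b in self.block_shape)
        if any(b <= 0 for b in bs):
            raise ValueError(f"block_shape must be positive, got {bs}")
        object.__setattr__(self, "block_shape", bs)
        object.__setattr__(
            self, "roi_blocks", frozenset(tuple(int(i) for i in b) for b in self.roi_blocks)
        )
        object.__setattr__(self, "origin", tuple(int(o) for o in self.origin))

    def block_bounds(
        self, index: Sequence[int]
    ) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
        start = tuple(o + i * b for o, i, b in zip(self.origin, index, self.block_shape))
        stop = tuple(s + b for s, b in zip(start, self.block_shape))
        return start, stop

    def sorted_blocks(self) -> list[tuple[int, int, int]]:
        return sorted(self.roi_blocks)

    def block_of_point(self, p: Sequence[int]) -> tuple[int, int, int]:
        return tuple(
            (int(c) - o) // b for c, o, b in zip(p, self.origin, self.block_shape)
        )


def label_at(volume: LabelVolume, p: Sequence[int]) -> int:
    """Return the segment id at global coordinate ``p``."""
    if not volume.contains(p):
        raise IndexError(
            f"point {tuple(int(c) for c in p)} outside volume bounds {volume.bounds}"
        )
    z, y, x = (int(c) - o for c, o in zip(p, volume.offset))
    return int(volume.data[z, y, x])


def _check_aligned(S: LabelVolume, G: LabelVolume) -> None:
    if S.data.shape != G.data.shape or S.offset != G.offset:
        raise ValueError(
            f"volumes are not aligned: shapes {S.data.shape}/{G.data.shape}, "
            f"offsets {S.offset}/{G.offset}"
        )


def build_contingency(
    S: LabelVolume,
    G: LabelVolume,
    domain: str = VOXELS,
    points: Iterable[Sequence[int]] | None = None,
) -> ContingencyTable:
    """Joint label counts of a test segmentation against a reference.

    For the voxel domain every aligned voxel pair with both labels nonzero
    contributes one count.  For the synapse-endpoint domain the supplied
    global coordinates are resolved in both volumes; each coordinate is one
    comparison point.  Points where either label is 0 are excluded and
    tallied in ``ignored``.
    """
    _check_aligned(S, G)
    if domain == VOXELS:
        s_flat = S.data.ravel()
        g_flat = G.data.ravel()
    elif domain == SYNAPSE_ENDPOINTS:
        pts = list(points or [])
        if not pts:
            raise ValueError("synapse_endpoints domain requires a nonempty point list")
        for p in pts:
            if not S.contains(p):
                raise IndexError(
                    f"point {tuple(int(c) for c in p)} outside volume bounds {S.bounds}"
                )
        idx = np.asarray([[int(c) - o for c, o in zip(p, S.offset)] for p in pts])
        s_flat = S.data[idx[:, 0], idx[:, 1], idx[:, 2]]
        g_flat = G.data[idx[:, 0], idx[:, 1], idx[:, 2]]
    else:
        raise ValueError(f"unknown domain {domain!r}")

    keep = (s_flat != 0) & (g_flat != 0)
    ignored = int(s_flat.size - keep.sum())
    pairs = np.stack([s_flat[keep], g_flat[keep]], axis=1)
    if pairs.size:
        uniq, cnt = np.unique(pairs, axis=0, return_counts=True)
        counts = {(int(s), int(g)): int(c) for (s, g), c in zip(uniq, cnt)}
    else:
        counts = {}
    return ContingencyTable(counts, domain_kind=domain, ignored=ignored)


def endpoint_coordinates(connections: Iterable[SynapseConnection]) -> list[tuple[int, int, int]]:
    """Flatten connections into comparison points: each contributes pre and post."""
    pts: list[tuple[int, int, int]] = []
    for c in connections:
        pts.append(c.pre)
        pts.append(c.post)
    return pts


def merge_contingency(a: ContingencyTable, b: ContingencyTable) -> ContingencyTable:
    """Entrywise sum of two tables over the same comparison domain."""
    if a.domain_kind != b.domain_kind:
        raise ValueError(
            f"cannot merge tables over different domains: "
            f"{a.domain_kind!r} vs {b.domain_kind!r}"
        )
    counts = dict(a.counts)
    for key, c in b.counts.items():
        counts[key] = counts.get(key, 0) + c
    return ContingencyTable(counts, domain_kind=a.domain_kind, ignored=a.ignored + b.ignored)
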