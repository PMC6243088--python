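"""Ground-truth-free segmentation statistics.

A segmentation can be screened without a reference by looking for
biologically implausible structure: orphans (fragments too small to be a
complete neuron, measured in voxels or synaptic endpoints), autapses
(connections of a segment onto itself, which in bulk flag false mergers),
and the number of segments needed to reach a volume-completeness threshold.
Per-block orphan densities feed the subvolume heat map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import GridSpec, LabelVolume, SynapseConnection, label_at

__all__ = [
    "OrphanReport",
    "SelfLoopReport",
    "orphan_count",
    "self_loop_report",
    "segments_to_threshold",
    "heatmap_export",
    "endpoint_counts",
    "voxel_counts",
]


@dataclass
class OrphanReport:
    """Segments below the plausibility size threshold K."""

    threshold_kind: str
    threshold: int
    orphan_labels: frozenset[int]
    sizes: dict[int, int]
    per_block_density: dict[tuple[int, int, int], int] = field(default_factory=dict)

    @property
    def count(self) -> int:
        return len(self.orphan_labels)


@dataclass
class SelfLoopReport:
    """Autapse statistics: connections whose pre and post sites share a segment."""

    total: int
    per_label: dict[int, int]
    outliers: list[tuple[int, int]]


def voxel_counts(volume: LabelVolume) -> dict[int, int]:
    """Voxel count per nonzero segment."""
    uniq, cnt = np.unique(volume.data, return_counts=True)
    return {int(u): int(c) for u, c in zip(uniq, cnt) if u != 0}


def endpoint_counts(
    volume: LabelVolume, connections: Iterable[SynapseConnection]
) -> dict[int, int]:
    """Synaptic endpoint count per nonzero segment (pre and post each count).

    Segments present in the volume but touched by no endpoint get count 0.
    """
    counts = {int(lab): 0 for lab in volume.labels()}
    for c in connections:
        for p in (c.pre, c.post):
            lab = label_at(volume, p)
            if lab != 0:
                counts[lab] = counts.get(lab, 0) + 1
    return counts


def _centroids(volume: LabelVolume) -> dict[int, tuple[float, float, float]]:
    """Size-weighted centroid (mean global voxel coordinate) per segment."""
    data = volume.data
    nz = data != 0
    labs = data[nz]
    coords = np.argwhere(nz)
    uniq, inv = np.unique(labs, return_inverse=True)
    sums = np.zeros((len(uniq), 3))
    np.add.at(sums, inv, coords)
    n = np.bincount(inv, minlength=len(uniq))
    cent = sums / n[:, None] + np.asarray(volume.offset)
    return {int(u): tuple(c) for u, c in zip(uniq, cent)}


def orphan_count(
    S: LabelVolume,
    connections: Iterable[SynapseConnection] | None = None,
    K: int = 10,
    kind: str = "synapse_endpoints",
    grid: GridSpec | None = None,
) -> OrphanReport:
    """Count segments strictly smaller than K.

    With ``kind='synapse_endpoints'`` (requires connections) size is the
    number of synaptic endpoints a segment hosts — a segment with none is
    trivially an orphan.  With ``kind='voxels'`` size is voxel count.  When
    a grid is given, orphans are also binned by the block containing their
    size-weighted centroid for the density heat map.
    """
    if kind == "synapse_endpoints":
        if connections is None:
            raise ValueError("endpoint-based orphan counting requires connections")
        sizes = endpoint_counts(S, connections)
    elif kind == "voxels":
        sizes = voxel_counts(S)
    else:
        raise ValueError(f"unknown size kind {kind!r}")
    orphans = frozenset(lab for lab, size in sizes.items() if size < K)
    density: dict[tuple[int, int, int], int] = {}
    if grid is not None and orphans:
        cent = _centroids(S)
        for lab in orphans:
            block = grid.block_of_point([int(c) for c in cent[lab]])
            density[block] = density.get(block, 0) + 1
    return OrphanReport(
        threshold_kind=kind,
        threshold=int(K),
        orphan_labels=orphans,
        sizes=sizes,
        per_block_density=density,
    )


def self_loop_report(
    S: LabelVolume, connections: Iterable[SynapseConnection]
) -> SelfLoopReport:
    """Count autapses and rank the segments carrying the most.

    Autapses do occur biologically, so heavy carriers are presented as
    ranked outliers to inspect rather than as hard errors.
    """
    connections = list(connections)
    if not connections:
        raise ValueError("self-loop report requires a nonempty connection list")
    per_label: dict[int, int] = {}
    total = 0
    for c in connections:
        a = label_at(S, c.pre)
        b = label_at(S, c.post)
        if a != 0 and a == b:
            total += 1
            per_label[a] = per_label.get(a, 0) + 1
    outliers = sorted(per_label.items(), key=lambda kv: (-kv[1], kv[0]))
    return SelfLoopReport(total=total, per_label=per_label, outliers=outliers)


def segments_to_threshold(sizes: Mapping[int, int], percent: float) -> int:
    """Minimal number of segments whose cumulative size reaches X% of the total.

    Segments are taken largest first; zero-size segments never contribute.
    """
    if not (0 < percent <= 100):
        raise ValueError(f"percent must lie in (0, 100], got {percent}")
    values = sorted((v for v in sizes.values() if v > 0), reverse=True)
    if not values:
        raise ValueError("no segments with positive size")
    target = percent / 100.0 * sum(values)
    cum = 0
    for i, v in enumerate(values, start=1):
        cum += v
        if cum >= target - 1e-9:
            return i
    return len(values)


def heatmap_export(
    per_block_values: Mapping[tuple[int, int, int], float],
    grid: GridSpec,
) -> pd.DataFrame:
    """Tabulate a per-block statistic for external heat-map plotting.

    One row per ROI block in deterministic (z, y, x) order; blocks without
    a value carry NaN as the explicit missing marker.
    """
    rows = []
    for index in grid.sorted_blocks():
        value = per_block_values.get(index, np.nan)
        rows.append({"block_z": index[0], "block_y": index[1], "block_x": index[2], "value": value})
    return pd.DataFrame(rows, columns=["block_z", "block_y", "block_x", "value"])
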