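"""The evaluation pipeline and its JSON report.

``run_evaluation`` wires the full workflow together: load inputs, restrict
to the ROI, apply the optional filters (sparse-body restriction,
ground-truth orphan removal, boundary dilation, downsampling), partition
into grid blocks, relabel with local-then-global connected components,
build per-block contingency tables, merge them, and compute every
applicable metric at summary, body, and subvolume granularity.  Each
per-block stage satisfies the mergeable-table contract, so the block loop
is a parallelism seam: results do not depend on the block shape.

Reports are deterministic: the same inputs and parameters always produce a
byte-identical JSON payload (no timestamps inside the hashed content).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import __version__
from .core import (
    ContingencyTable,
    GridSpec,
    LabelVolume,
    SynapseConnection,
    build_contingency,
    endpoint_coordinates,
    merge_contingency,
)
from .io import read_roi, read_synapses, read_volume
from .preprocess import (
    ComponentRelabeling,
    apply_relabeling,
    dilate_gt_boundaries,
    downsample_labels,
    extract_block,
    filter_small_orphans_gt,
    filter_sparse_bodies,
    global_connected_components,
    local_connected_components,
    partition_grid,
)
from .supervised import (
    best_bodies_by_overlap,
    body_connection_coverage,
    body_under_over,
    cc_thresholded,
    connection_graph,
    connectivity_correctness,
    frag,
    frag_thresholded,
    match_segments,
    rand_index,
    subvolume_vi,
    vi,
)
from .unsupervised import (
    endpoint_counts,
    orphan_count,
    self_loop_report,
    segments_to_threshold,
    voxel_counts,
)

__all__ = ["EvaluationConfig", "EvaluationReport", "run_evaluation", "compare_reports"]

SCHEMA_VERSION = 1

#: orientation of each summary metric prefix: +1 higher is better, -1 lower
_ORIENTATION = {
    "vi_split": -1,
    "vi_merge": -1,
    "vi_total": -1,
    "rand": 1,
    "adjusted_rand": 1,
    "frag": -1,
    "frag_threshold": -1,
    "cc": 1,
    "reccc": 1,
    "preccc": 1,
    "orphan": -1,
    "autapse": -1,
    "segments_to": -1,
}


@dataclass
class EvaluationConfig:
    """Inputs and parameters of one evaluation run.

    Volumes and synapses may be given in memory or as file paths.  Defaults
    follow common practice for EM evaluation: 64-voxel grid blocks,
    ground-truth boundary dilation of radius 2, orphans defined as fewer
    than 10 synaptic endpoints, completeness levels 50/75/90%, and
    connection-path thresholds k=0 and k=9 (paths of at least 10 synapses).
    """

    test: LabelVolume | str = None
    groundtruth: LabelVolume | str | None = None
    synapses: Sequence[SynapseConnection] | str | None = None
    roi: GridSpec | str | None = None
    block_shape: tuple[int, int, int] = (64, 64, 64)
    dilation_radius: int = 2
    sparse: bool = False
    gt_min_size: int = 0
    downsample: int = 1
    self_compare: bool = False
    connectivity: bool | None = None
    orphan_threshold: int = 10
    completeness_percents: tuple[float, ...] = (50.0, 75.0, 90.0)
    cc_thresholds: tuple[int, ...] = (0, 9)
    match_method: str = "greedy"
    top_n_bodies: int = 50
    seed: int = 0

    def resolve(self) -> "EvaluationConfig":
        cfg = EvaluationConfig(**{**self.__dict__})
        if isinstance(cfg.test, str):
            cfg.test = read_volume(cfg.test)
        if isinstance(cfg.groundtruth, str):
            cfg.groundtruth = read_volume(cfg.groundtruth)
        if isinstance(cfg.synapses, str):
            cfg.synapses = read_synapses(cfg.synapses)
        if isinstance(cfg.roi, str):
            cfg.roi = read_roi(cfg.roi)
        return cfg

    def params_dict(self) -> dict:
        return {
            "block_shape": list(self.block_shape),
            "dilation_radius": self.dilation_radius,
            "sparse": self.sparse,
            "gt_min_size": self.gt_min_size,
            "downsample": self.downsample,
            "self_compare": self.self_compare,
            "orphan_threshold": self.orphan_threshold,
            "completeness_percents": list(self.completeness_percents),
            "cc_thresholds": list(self.cc_thresholds),
            "match_method": self.match_method,
            "top_n_bodies": self.top_n_bodies,
            "seed": self.seed,
        }


@dataclass
class EvaluationReport:
    """Nested record of summary, per-body, subvolume, and unsupervised stats."""

    metadata: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    bodies: dict = field(default_factory=dict)
    subvolumes: dict = field(default_factory=dict)
    unsupervised: dict = field(default_factory=dict)

    def to_payload(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "metadata": self.metadata,
            "summary": self.summary,
            "bodies": self.bodies,
            "subvolumes": self.subvolumes,
            "unsupervised": self.unsupervised,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_payload(), sort_keys=True, indent=1, allow_nan=True)

    def save(self, path: str) -> None:
        with open(path, "w") as f:
            f.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        payload = json.loads(text)
        return cls(
            metadata=payload.get("metadata", {}),
            summary=payload.get("summary", {}),
            bodies=payload.get("bodies", {}),
            subvolumes=payload.get("subvolumes", {}),
            unsupervised=payload.get("unsupervised", {}),
        )

    @classmethod
    def load(cls, path: str) -> "EvaluationReport":
        with open(path) as f:
            return cls.from_json(f.read())

    def flat_summary(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for domain, metrics in self.summary.items():
            for name, value in metrics.items():
                if isinstance(value, (int, float)) and value is not None:
                    out[f"{domain}.{name}"] = value
        for name, value in self.unsupervised.items():
            if isinstance(value, (int, float)):
                out[f"unsupervised.{name}"] = value
        return out


def _block_key(index: Sequence[int]) -> str:
    return ",".join(str(int(i)) for i in index)


def _restrict_to_roi(volume: LabelVolume, grid: GridSpec) -> LabelVolume:
    """Zero out voxels outside the ROI blocks."""
    mask = np.zeros(volume.shape, dtype=bool)
    vstart, vstop = volume.bounds
    for index in grid.roi_blocks:
        bstart, bstop = grid.block_bounds(index)
        lo = tuple(max(a, b) for a, b in zip(bstart, vstart))
        hi = tuple(min(a, b) for a, b in zip(bstop, vstop))
        if any(h <= l for l, h in zip(lo, hi)):
            continue
        sl = tuple(slice(l - o, h - o) for l, h, o in zip(lo, hi, volume.offset))
        mask[sl] = True
    return volume.with_data(np.where(mask, volume.data, 0))


def _blockwise_cc(
    volume: LabelVolume, grid: GridSpec
) -> tuple[LabelVolume, dict[tuple[int, int, int], LabelVolume], ComponentRelabeling]:
    """Local connected components per block, stitched by global components.

    Returns the relabeled whole volume, the relabeled blocks, and the
    composed relabeling whose provenance traces final labels to original
    segment ids.
    """
    blocks: list[tuple[tuple[int, int, int], LabelVolume, ComponentRelabeling]] = []
    next_label = 1
    locals_: dict[tuple[int, int, int], tuple[LabelVolume, ComponentRelabeling]] = {}
    for index in grid.sorted_blocks():
        try:
            block = extract_block(volume, grid, index)
        except ValueError:
            continue
        relabeled, rel = local_connected_components(block, start_label=next_label)
        if rel.provenance:
            next_label = max(rel.provenance) + 1
        locals_[index] = (relabeled, rel)
        blocks.append((index, relabeled, rel))
    global_rel = global_connected_components(blocks, grid)

    merged_local = ComponentRelabeling()
    for _, (_, rel) in locals_.items():
        merged_local.provenance.update(rel.provenance)
    composed = merged_local.compose(global_rel)

    out_blocks: dict[tuple[int, int, int], LabelVolume] = {}
    stitched = np.zeros(volume.shape, dtype=np.int64)
    for index, (relabeled, _) in locals_.items():
        final_block = apply_relabeling(relabeled, global_rel)
        out_blocks[index] = final_block
        sl = tuple(
            slice(s - o, s - o + n)
            for s, o, n in zip(final_block.offset, volume.offset, final_block.shape)
        )
        stitched[sl] = final_block.data
    return volume.with_data(stitched), out_blocks, composed


def _merge_block_tables(
    S_blocks: Mapping[tuple[int, int, int], LabelVolume],
    G_blocks: Mapping[tuple[int, int, int], LabelVolume],
    domain: str,
    points_by_block: Mapping[tuple[int, int, int], list] | None = None,
) -> ContingencyTable:
    table = ContingencyTable(domain_kind=domain)
    for index in sorted(S_blocks):
        if index not in G_blocks:
            continue
        if domain == "voxels":
            part = build_contingency(S_blocks[index], G_blocks[index], domain)
        else:
            pts = (points_by_block or {}).get(index, [])
            if not pts:
                continue
            part = build_contingency(S_blocks[index], G_blocks[index], domain, points=pts)
        table = merge_contingency(table, part)
    return table


def _group_points_by_block(
    points: Iterable[Sequence[int]], grid: GridSpec
) -> dict[tuple[int, int, int], list]:
    out: dict[tuple[int, int, int], list] = {}
    for p in points:
        block = grid.block_of_point(p)
        if block in grid.roi_blocks:
            out.setdefault(block, []).append(tuple(int(c) for c in p))
    return out


def _summary_for_table(
    table: ContingencyTable, percents: Sequence[float]
) -> dict[str, float]:
    score = vi(table)
    out = {
        "vi_split": score.oversegmentation,
        "vi_merge": score.undersegmentation,
        "vi_total": score.total,
        "rand": rand_index(table),
        "adjusted_rand": rand_index(table, adjusted=True),
        "frag": frag(table),
        "n_test_segments": len(table.marginal_s()),
        "n_ref_segments": len(table.marginal_g()),
        "comparison_points": table.total,
        "ignored_points": table.ignored,
    }
    sizes_s = table.marginal_s()
    sizes_g = table.marginal_g()
    for pct in percents:
        cs, cg, diff = frag_thresholded(sizes_s, sizes_g, pct)
        out[f"frag_threshold_{pct:g}_test"] = cs
        out[f"frag_threshold_{pct:g}_ref"] = cg
        out[f"frag_threshold_{pct:g}_diff"] = diff
    return out


def run_evaluation(config: EvaluationConfig) -> EvaluationReport:
    """Execute the full evaluation pipeline and collect the report."""
    cfg = config.resolve()
    if cfg.test is None:
        raise ValueError("a test segmentation is required")
    S: LabelVolume = cfg.test
    G: LabelVolume | None = cfg.groundtruth
    if G is None and not cfg.self_compare:
        raise ValueError(
            "no reference volume given: supply --groundtruth or use self-compare mode"
        )
    connections = list(cfg.synapses) if cfg.synapses is not None else None
    if cfg.connectivity and connections is None:
        raise ValueError("connectivity metrics requested but no synapses supplied")
    want_connectivity = (
        cfg.connectivity if cfg.connectivity is not None else connections is not None
    )

    stages: list[dict] = []

    # --- ROI restriction
    if cfg.roi is not None:
        grid0 = cfg.roi
        S = _restrict_to_roi(S, grid0)
        if G is not None:
            G = _restrict_to_roi(G, grid0)

    # --- filters
    if G is not None:
        if cfg.gt_min_size > 0:
            G = filter_small_orphans_gt(G, cfg.gt_min_size)
        if cfg.sparse:
            S, G = filter_sparse_bodies(S, G)
        if cfg.dilation_radius > 0:
            G = dilate_gt_boundaries(G, cfg.dilation_radius)

    # --- downsampling
    if cfg.downsample > 1:
        S = downsample_labels(S, cfg.downsample)
        if G is not None:
            G = downsample_labels(G, cfg.downsample)
        if connections is not None:
            connections = [
                SynapseConnection(
                    pre=tuple(c // cfg.downsample for c in conn.pre),
                    post=tuple(c // cfg.downsample for c in conn.post),
                    id=conn.id,
                )
                for conn in connections
            ]
            connections = [c for c in connections if c.pre != c.post]

    grid = partition_grid(S.bounds, cfg.block_shape)

    # --- connected components, blockwise
    S_cc, S_blocks, S_rel = _blockwise_cc(S, grid)
    stages.append({"stage": "local+global CC (test)", "segments": len(np.unique(S_cc.data)) - 1})
    if G is not None:
        G_cc, G_blocks, G_rel = _blockwise_cc(G, grid)
        stages.append(
            {"stage": "local+global CC (reference)", "segments": len(np.unique(G_cc.data)) - 1}
        )

    report = EvaluationReport(
        metadata={
            "tool": "conneval",
            "version": __version__,
            "schema_version": SCHEMA_VERSION,
            "parameters": cfg.params_dict(),
            "mode": "self_compare" if cfg.self_compare else "supervised",
            "n_connections": len(connections) if connections is not None else 0,
            "stages": stages,
        }
    )

    # --- unsupervised statistics (always available)
    if connections is not None:
        orphans = orphan_count(
            S_cc, connections, K=cfg.orphan_threshold, kind="synapse_endpoints", grid=grid
        )
        loops = self_loop_report(S_cc, connections)
        report.unsupervised["autapse_total"] = loops.total
        report.unsupervised["autapse_outliers"] = [
            {"label": int(lab), "original_label": int(S_rel.original(lab)), "count": int(c)}
            for lab, c in loops.outliers[: cfg.top_n_bodies]
        ]
        sizes_for_threshold = endpoint_counts(S_cc, connections)
    else:
        orphans = orphan_count(S_cc, K=cfg.orphan_threshold, kind="voxels", grid=grid)
        sizes_for_threshold = voxel_counts(S_cc)
    report.unsupervised["orphan_count"] = orphans.count
    report.unsupervised["orphan_threshold"] = orphans.threshold
    report.unsupervised["orphan_threshold_kind"] = orphans.threshold_kind
    for pct in cfg.completeness_percents:
        report.unsupervised[f"segments_to_{pct:g}pct"] = segments_to_threshold(
            sizes_for_threshold, pct
        )
    report.subvolumes["orphan_density"] = {
        _block_key(b): int(c) for b, c in sorted(orphans.per_block_density.items())
    }

    if G is None:
        return report

    # --- contingency tables, per block then merged
    voxel_table = _merge_block_tables(S_blocks, G_blocks, "voxels")
    if voxel_table.total == 0:
        raise ValueError("no comparison points: the volumes share no labeled voxels")
    report.summary["voxels"] = _summary_for_table(voxel_table, cfg.completeness_percents)

    endpoint_table = None
    if connections is not None:
        pts = endpoint_coordinates(connections)
        pts_by_block = _group_points_by_block(pts, grid)
        endpoint_table = _merge_block_tables(
            S_blocks, G_blocks, "synapse_endpoints", pts_by_block
        )
        if endpoint_table.total:
            report.summary["synapse_endpoints"] = _summary_for_table(
                endpoint_table, cfg.completeness_percents
            )

    # --- connectivity metrics
    if want_connectivity and endpoint_table is not None and endpoint_table.total:
        assignment = match_segments(endpoint_table, method=cfg.match_method)
        Sg = connection_graph(S_cc, connections)
        Gg = connection_graph(G_cc, connections)
        cc_section = report.summary.setdefault("synapse_endpoints", {})
        if Gg.n_connections:
            cc_section["cc"] = connectivity_correctness(Sg, Gg, assignment)
            for k in cfg.cc_thresholds:
                rec, pre = cc_thresholded(Sg, Gg, assignment, k)
                cc_section[f"reccc_{k}"] = rec
                cc_section[f"preccc_{k}"] = pre
        cc_section["unresolved_connections_test"] = Sg.unresolved
        cc_section["unresolved_connections_ref"] = Gg.unresolved
        coverage = body_connection_coverage(Gg, Sg, assignment) if Gg.n_connections else {}
    else:
        assignment = None
        coverage = {}

    # --- per-body statistics
    body_table = endpoint_table if (endpoint_table is not None and endpoint_table.total) else voxel_table
    overlap = dict(best_bodies_by_overlap(body_table))
    bodies = []
    for g in sorted(body_table.marginal_g()):
        over, under = body_under_over(body_table, g)
        bodies.append(
            {
                "label": int(g),
                "original_label": int(G_rel.original(g)),
                "vi_over": over,
                "vi_under": under,
                "connection_coverage": coverage.get(g),
                "largest_overlap_fraction": overlap[g],
            }
        )
    bodies.sort(key=lambda b: (-(b["vi_over"] + b["vi_under"]), b["label"]))
    report.bodies["domain"] = body_table.domain_kind
    report.bodies["worst"] = bodies[: cfg.top_n_bodies]
    if bodies:
        worst = bodies[0]
        report.summary.setdefault(body_table.domain_kind, {})["worst_body_vi"] = (
            worst["vi_over"] + worst["vi_under"]
        )

    # --- subvolume metrics
    sub_vi = subvolume_vi(S_blocks, G_blocks, grid)
    report.subvolumes["vi"] = {
        _block_key(b): (
            None if score is None else {"split": score.oversegmentation, "merge": score.undersegmentation}
        )
        for b, score in sorted(sub_vi.items())
    }
    return report


def compare_reports(a: EvaluationReport, b: EvaluationReport) -> dict:
    """Side-by-side summary comparison with per-metric orientation.

    Metrics present in only one report are listed as warnings; the
    comparison proceeds on the intersection.
    """
    fa, fb = a.flat_summary(), b.flat_summary()
    shared = sorted(set(fa) & set(fb))
    only_a = sorted(set(fa) - set(fb))
    only_b = sorted(set(fb) - set(fa))
    rows = []
    for key in shared:
        va, vb = fa[key], fb[key]
        orient = 0
        name = key.split(".", 1)[1]
        for prefix, o in _ORIENTATION.items():
            if name.startswith(prefix):
                orient = o
                break
        if orient == 0 or va == vb:
            better = "tie" if va == vb else "n/a"
        else:
            better = "a" if (va - vb) * orient > 0 else "b"
        rows.append({"metric": key, "a": va, "b": vb, "difference": va - vb, "better": better})
    warnings = []
    if only_a:
        warnings.append(f"metrics only in a: {only_a}")
    if only_b:
        warnings.append(f"metrics only in b: {only_b}")
    return {"rows": rows, "warnings": warnings}
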