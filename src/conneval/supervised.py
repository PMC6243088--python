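"""Metrics comparing a test segmentation S against a reference G.

Covers the information-theoretic scores (variation of information and its
per-body decompositions), pair-counting scores (Rand index, plain and
chance-adjusted), segment matching by greatest overlap, the synapse-aware
connectivity-correctness family, fragmentation counts, per-body connection
coverage, and subvolume-resolved VI.

All entropies are in bits (logarithm base 2).  Probabilities are empirical
frequencies over the comparison points of the contingency table: ``P(g)``
is the fraction of comparison points carrying reference label ``g``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import ContingencyTable, GridSpec, LabelVolume, SynapseConnection, label_at
from .preprocess import local_connected_components
from .unsupervised import segments_to_threshold

__all__ = [
    "ViScore",
    "Assignment",
    "ConnectionGraph",
    "BodyStats",
    "vi",
    "rand_index",
    "body_vi_decomposition",
    "body_under_over",
    "match_segments",
    "connection_graph",
    "connectivity_correctness",
    "cc_thresholded",
    "frag",
    "frag_thresholded",
    "body_connection_coverage",
    "best_bodies_by_overlap",
    "subvolume_vi",
]


@dataclass(frozen=True)
class ViScore:
    """Variation of information split into its two error components (bits).

    ``oversegmentation`` is H(S|G): how much a reference segment is shattered
    across test segments (split errors).  ``undersegmentation`` is H(G|S):
    how much a test segment spans several reference segments (merge errors).
    """

    oversegmentation: float
    undersegmentation: float

    @property
    def total(self) -> float:
        return self.oversegmentation + self.undersegmentation


@dataclass
class Assignment:
    """One-to-one partial mapping from reference labels to test labels.

    ``mapping[g] = s`` means reference segment g is represented by test
    segment s; no test segment represents two reference segments.
    ``overlap_weight[g]`` is the comparison-point overlap of the matched pair.
    """

    mapping: dict[int, int] = field(default_factory=dict)
    overlap_weight: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = list(self.mapping.values())
        if len(values) != len(set(values)):
            raise ValueError("assignment is not injective")

    def get(self, g: int) -> int | None:
        return self.mapping.get(g)

    def total_weight(self) -> int:
        return sum(self.overlap_weight.values())


@dataclass
class ConnectionGraph:
    """Synapse connections resolved to ordered (pre label, post label) edges.

    ``edges[(a, b)]`` is the set of connection ids whose pre site resolved to
    segment a and post site to segment b; ``unresolved`` counts connections
    with either endpoint on background.
    """

    edges: dict[tuple[int, int], frozenset] = field(default_factory=dict)
    unresolved: int = 0

    @property
    def n_connections(self) -> int:
        return sum(len(ids) for ids in self.edges.values())

    def weight(self, pair: tuple[int, int]) -> int:
        return len(self.edges.get(pair, ()))


@dataclass(frozen=True)
class BodyStats:
    """Per-reference-body error summary."""

    label: int
    vi_over: float
    vi_under: float
    connection_coverage: float | None
    largest_overlap_fraction: float


def _require_nonempty(t: ContingencyTable) -> int:
    total = t.total
    if total == 0:
        raise ValueError("no comparison points: contingency table is empty")
    return total


def vi(t: ContingencyTable) -> ViScore:
    """Variation of information of the joint label distribution, in bits."""
    total = _require_nonempty(t)
    size_g = t.marginal_g()
    size_s = t.marginal_s()
    over = 0.0
    under = 0.0
    for (s, g), c in t.counts.items():
        p = c / total
        over += p * math.log2(size_g[g] / c)
        under += p * math.log2(size_s[s] / c)
    return ViScore(oversegmentation=over, undersegmentation=under)


def _pairs(n: int) -> int:
    return n * (n - 1) // 2


def rand_index(t: ContingencyTable, adjusted: bool = False) -> float:
    """Pair-counting agreement between the two labelings.

    The plain index is the fraction of comparison-point pairs on which the
    two labelings agree (same segment in both, or different in both).  The
    adjusted variant applies the Hubert-Arabie correction for chance and may
    be negative.
    """
    total = t.total
    if total < 2:
        raise ValueError(f"rand index needs at least 2 comparison points, got {total}")
    sum_nij = sum(_pairs(c) for c in t.counts.values())
    sum_a = sum(_pairs(c) for c in t.marginal_s().values())
    sum_b = sum(_pairs(c) for c in t.marginal_g().values())
    n_pairs = _pairs(total)
    if not adjusted:
        return (n_pairs + 2 * sum_nij - sum_a - sum_b) / n_pairs
    expected = sum_a * sum_b / n_pairs
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return (sum_nij - expected) / (max_index - expected)


def body_vi_decomposition(t: ContingencyTable) -> dict[int, float]:
    """Split H(S|G) into one non-negative term per reference body.

    Returns ``{g: P(g) * H(S | G=g)}``; the values sum to the
    oversegmentation component of :func:`vi`.  Apply to the transposed table
    for the per-test-segment undersegmentation decomposition.
    """
    total = _require_nonempty(t)
    size_g = t.marginal_g()
    out = {g: 0.0 for g in size_g}
    for (s, g), c in t.counts.items():
        out[g] += (c / total) * math.log2(size_g[g] / c)
    return out


def _binary_entropy(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -p * math.log2(p) - (1.0 - p) * math.log2(1.0 - p)


def body_under_over(t: ContingencyTable, g: int) -> tuple[float, float]:
    """Over- and under-segmentation scores of one reference body, in bits.

    The over term is this body's share of H(S|G): how badly g is shattered.
    The under term sums, over test segments s touching g, the segment-size
    weighted binary entropy of membership in g within s: how badly g is
    entangled with other bodies through false merges.
    """
    total = _require_nonempty(t)
    size_g = t.marginal_g()
    if g not in size_g:
        raise KeyError(f"reference label {g} not present in the contingency table")
    size_s = t.marginal_s()
    over = 0.0
    under = 0.0
    for (s, gg), c in t.counts.items():
        if gg != g:
            continue
        over += (c / total) * math.log2(size_g[g] / c)
        under += (size_s[s] / total) * _binary_entropy(c / size_s[s])
    return over, under


def match_segments(t: ContingencyTable, method: str = "greedy") -> Assignment:
    """One-to-one partial matching of reference to test segments by overlap.

    ``greedy`` scans candidate pairs by decreasing overlap (ties: smaller
    test label, then smaller reference label) and accepts a pair when both
    labels are still free.  ``optimal`` maximises total matched overlap with
    the Hungarian algorithm.  Reference labels with no acceptable partner
    stay unmatched.
    """
    if not t.counts:
        raise ValueError("cannot match segments of an empty contingency table")
    if method == "greedy":
        candidates = sorted(t.counts.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))
        used_s: set[int] = set()
        mapping: dict[int, int] = {}
        weight: dict[int, int] = {}
        for (s, g), c in candidates:
            if s in used_s or g in mapping:
                continue
            used_s.add(s)
            mapping[g] = s
            weight[g] = c
        return Assignment(mapping=mapping, overlap_weight=weight)
    if method == "optimal":
        s_labels = sorted(t.marginal_s())
        g_labels = sorted(t.marginal_g())
        s_index = {s: i for i, s in enumerate(s_labels)}
        g_index = {g: j for j, g in enumerate(g_labels)}
        w = np.zeros((len(g_labels), len(s_labels)))
        for (s, g), c in t.counts.items():
            w[g_index[g], s_index[s]] = c
        rows, cols = linear_sum_assignment(w, maximize=True)
        mapping: dict[int, int] = {}
        weight: dict[int, int] = {}
        for i, j in zip(rows, cols):
            c = int(w[i, j])
            if c > 0:
                mapping[g_labels[i]] = s_labels[j]
                weight[g_labels[i]] = c
        return Assignment(mapping=mapping, overlap_weight=weight)
    raise ValueError(f"unknown matching method {method!r}")


def connection_graph(
    labeling: LabelVolume, connections: Iterable[SynapseConnection]
) -> ConnectionGraph:
    """Resolve synapse connections to directed segment-pair edges.

    Each connection becomes one element of the edge multiset
    ``(label at pre) -> (label at post)``; connections touching background
    (label 0) at either site are excluded and counted as unresolved.
    """
    edges: dict[tuple[int, int], set] = {}
    unresolved = 0
    for c in connections:
        a = label_at(labeling, c.pre)
        b = label_at(labeling, c.post)
        if a == 0 or b == 0:
            unresolved += 1
            continue
        edges.setdefault((a, b), set()).add(c.id)
    return ConnectionGraph(
        edges={k: frozenset(v) for k, v in edges.items()}, unresolved=unresolved
    )


def _matched_ids(
    Gg: ConnectionGraph, Sg: ConnectionGraph, A: Assignment
) -> dict[tuple[int, int], frozenset]:
    """Per ground-truth pair, the connection ids preserved under the assignment."""
    out: dict[tuple[int, int], frozenset] = {}
    for (gi, gj), ids in Gg.edges.items():
        si, sj = A.get(gi), A.get(gj)
        if si is None or sj is None:
            out[(gi, gj)] = frozenset()
            continue
        out[(gi, gj)] = ids & Sg.edges.get((si, sj), frozenset())
    return out


def connectivity_correctness(
    Sg: ConnectionGraph, Gg: ConnectionGraph, A: Assignment
) -> float:
    """Fraction of ground-truth synaptic connections preserved by S.

    A ground-truth connection between bodies (gi, gj) counts as preserved
    when the same physical synapse (same connection id) also links the
    matched test segments (A(gi), A(gj)).  Because the assignment is
    one-to-one, a false merge of two bodies forfeits the connections of at
    least one of them; a false split forfeits connections landing on the
    unmatched fragments.
    """
    denom = Gg.n_connections
    if denom == 0:
        raise ValueError("no ground-truth connections to score")
    matched = _matched_ids(Gg, Sg, A)
    num = sum(len(ids) for ids in matched.values())
    return num / denom


def cc_thresholded(
    Sg: ConnectionGraph,
    Gg: ConnectionGraph,
    A: Assignment,
    k: int,
    inclusive: bool = False,
) -> tuple[float | None, float | None]:
    """Recall and precision of strong connection paths.

    A segment pair is a strong path when its connection count exceeds ``k``
    (or reaches ``k`` with ``inclusive``).  Recall is the fraction of strong
    ground-truth pairs whose preserved-connection count is itself above the
    threshold; precision replaces the denominator with the number of strong
    test pairs.  An empty denominator yields ``None`` (undefined), never 0.
    """
    if k < 0:
        raise ValueError("threshold k must be non-negative")

    def above(w: int) -> bool:
        return w >= k if inclusive else w > k

    matched = _matched_ids(Gg, Sg, A)
    num = sum(1 for ids in matched.values() if above(len(ids)))
    rec_den = sum(1 for ids in Gg.edges.values() if above(len(ids)))
    pre_den = sum(1 for ids in Sg.edges.values() if above(len(ids)))
    recall = num / rec_den if rec_den else None
    precision = num / pre_den if pre_den else None
    return recall, precision


def frag(t: ContingencyTable) -> int:
    """Excess of test segments over reference segments in the comparison domain.

    A lower bound on the merge edits needed to turn S into G; negative when
    S is the more merged of the two.
    """
    return len(t.marginal_s()) - len(t.marginal_g())


def frag_thresholded(
    sizes_S: Mapping[int, int],
    sizes_G: Mapping[int, int],
    percent: float,
) -> tuple[int, int, int]:
    """Segments needed for an X%-complete connectome, in S and in G.

    Counts, for each volume, the smallest set of segments (taken largest
    first) whose cumulative size reaches ``percent`` of that volume's total;
    returns ``(count_S, count_G, count_S - count_G)``.
    """
    count_s = segments_to_threshold(sizes_S, percent)
    count_g = segments_to_threshold(sizes_G, percent)
    return count_s, count_g, count_s - count_g


def body_connection_coverage(
    Gg: ConnectionGraph, Sg: ConnectionGraph, A: Assignment
) -> dict[int, float]:
    """Per reference body, the fraction of its connections preserved by S.

    A connection is incident to body g when g is its pre or post segment.
    Bodies with no incident connections are omitted.
    """
    matched = _matched_ids(Gg, Sg, A)
    incident: dict[int, int] = {}
    covered: dict[int, int] = {}
    for (gi, gj), ids in Gg.edges.items():
        ok = len(matched[(gi, gj)])
        for g in {gi, gj}:
            incident[g] = incident.get(g, 0) + len(ids)
            covered[g] = covered.get(g, 0) + ok
    return {g: covered[g] / incident[g] for g in incident}


def best_bodies_by_overlap(t: ContingencyTable) -> list[tuple[int, float]]:
    """Rank reference bodies by how much a single test segment covers them.

    For each body g the score is ``max_s counts[(s, g)] / size(g)``; 1.0
    means one test segment contains the body entirely.  Ranked descending,
    ties broken by smaller label.
    """
    if not t.counts:
        raise ValueError("cannot rank bodies of an empty contingency table")
    size_g = t.marginal_g()
    best: dict[int, int] = {}
    for (s, g), c in t.counts.items():
        if c > best.get(g, 0):
            best[g] = c
    ranked = [(g, best[g] / size_g[g]) for g in size_g]
    ranked.sort(key=lambda kv: (-kv[1], kv[0]))
    return ranked


def subvolume_vi(
    S_blocks: Mapping[tuple[int, int, int], LabelVolume],
    G_blocks: Mapping[tuple[int, int, int], LabelVolume],
    grid: GridSpec,
) -> dict[tuple[int, int, int], ViScore | None]:
    """VI per grid block, each block treated as an isolated segmentation.

    Both volumes are relabeled with local connected components inside the
    block first, so an error whose cause lies elsewhere does not bleed VI
    into blocks it merely passes through.  Blocks with no comparison points
    map to ``None``.
    """
    from .core import build_contingency

    out: dict[tuple[int, int, int], ViScore | None] = {}
    for index in sorted(grid.roi_blocks):
        if index not in S_blocks or index not in G_blocks:
            continue
        s_local, _ = local_connected_components(S_blocks[index])
        g_local, _ = local_connected_components(G_blocks[index])
        table = build_contingency(s_local, g_local)
        out[index] = vi(table) if table.total else None
    return out
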