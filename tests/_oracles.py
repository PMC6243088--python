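"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's contingency-table code paths:
VI is computed from the joint distribution assembled with a plain Python
dictionary loop, the Rand index by enumerating every comparison-point
pair, and connectivity correctness by replaying a corruption log against
the raw connection list.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


def brute_vi(s_labels: np.ndarray, g_labels: np.ndarray) -> tuple[float, float]:
    """(H(S|G), H(G|S)) in bits over points where both labels are nonzero."""
    joint: Counter = Counter()
    for s, g in zip(s_labels.ravel().tolist(), g_labels.ravel().tolist()):
        if s != 0 and g != 0:
            joint[(s, g)] += 1
    n = sum(joint.values())
    ps: Counter = Counter()
    pg: Counter = Counter()
    for (s, g), c in joint.items():
        ps[s] += c
        pg[g] += c
    h_joint = -sum((c / n) * math.log2(c / n) for c in joint.values())
    h_s = -sum((c / n) * math.log2(c / n) for c in ps.values())
    h_g = -sum((c / n) * math.log2(c / n) for c in pg.values())
    return h_joint - h_g, h_joint - h_s


def brute_rand(s_labels: np.ndarray, g_labels: np.ndarray, adjusted: bool = False) -> float:
    """Rand index by enumerating all pairs of comparison points."""
    s = s_labels.ravel()
    g = g_labels.ravel()
    keep = (s != 0) & (g != 0)
    s, g = s[keep], g[keep]
    same_s = s[:, None] == s[None, :]
    same_g = g[:, None] == g[None, :]
    iu = np.triu_indices(len(s), k=1)
    agree = (same_s[iu] == same_g[iu]).sum()
    n_pairs = len(iu[0])
    if not adjusted:
        return agree / n_pairs
    both = (same_s[iu] & same_g[iu]).sum()
    sum_a = same_s[iu].sum()
    sum_b = same_g[iu].sum()
    expected = sum_a * sum_b / n_pairs
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return (both - expected) / (max_index - expected)


def replay_endpoint_label(point, gt_label: int, corruption_log: list[dict]) -> int:
    """Track the test-volume label of one ground-truth point through a log."""
    label = gt_label
    for entry in corruption_log:
        if entry["op"] == "split":
            if label == entry["label"] and point[entry["axis"]] >= entry["plane"]:
                label = entry["new_label"]
        elif entry["op"] == "merge":
            if label in (entry["a"], entry["b"]):
                label = entry["into"]
        # boundary shifts never move synapse endpoints
    return label


def replay_cc(scene) -> float:
    """Predict connectivity correctness from the corruption log alone.

    Resolves every endpoint's corrupted label geometrically from the log,
    rebuilds the endpoint-overlap counts, applies the same greedy matching
    rule (largest overlap, ties to smaller test then reference label), and
    counts preserved connections — without touching any label volume.
    """
    gt = scene.ground_truth
    gt_label = lambda p: int(gt.data[p])
    overlaps: Counter = Counter()
    resolved = []
    for c in scene.connections:
        g_pre, g_post = gt_label(c.pre), gt_label(c.post)
        s_pre = replay_endpoint_label(c.pre, g_pre, scene.corruption_log)
        s_post = replay_endpoint_label(c.post, g_post, scene.corruption_log)
        overlaps[(s_pre, g_pre)] += 1
        overlaps[(s_post, g_post)] += 1
        resolved.append(((g_pre, g_post), (s_pre, s_post)))
    assignment: dict[int, int] = {}
    used_s: set[int] = set()
    for (s, g), _ in sorted(overlaps.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1])):
        if s in used_s or g in assignment:
            continue
        assignment[g] = s
        used_s.add(s)
    matched = sum(
        1
        for (g_pre, g_post), (s_pre, s_post) in resolved
        if assignment.get(g_pre) == s_pre and assignment.get(g_post) == s_post
    )
    return matched / len(resolved)
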