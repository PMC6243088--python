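import math

import numpy as np
import pytest

from conneval import (
    ContingencyTable,
    LabelVolume,
    SynapseConnection,
    best_bodies_by_overlap,
    body_connection_coverage,
    body_under_over,
    body_vi_decomposition,
    build_contingency,
    cc_thresholded,
    connection_graph,
    connectivity_correctness,
    frag,
    frag_thresholded,
    match_segments,
    partition_grid,
    rand_index,
    subvolume_vi,
    vi,
)
from conneval.preprocess import extract_block
from conneval.supervised import Assignment, ConnectionGraph

from conftest import random_table, random_volume
from _oracles import brute_rand, brute_vi


def make_toy_graphs():
    """G edges 1->2 with ids c1..c3; S resolves c1,c2 to (10,20) and c3 to (10,21)."""
    Gg = ConnectionGraph(edges={(1, 2): frozenset({"c1", "c2", "c3"})})
    Sg = ConnectionGraph(
        edges={(10, 20): frozenset({"c1", "c2"}), (10, 21): frozenset({"c3"})}
    )
    A = Assignment(mapping={1: 10, 2: 20}, overlap_weight={1: 3, 2: 2})
    return Sg, Gg, A


class TestVi:
    def test_diagonal_is_zero(self):
        t = ContingencyTable({(1, 1): 5, (2, 2): 3})
        score = vi(t)
        assert score.oversegmentation == score.undersegmentation == 0.0

    def test_worked_example(self, toy_table):
        score = vi(toy_table)
        assert score.oversegmentation == pytest.approx(0.5, abs=1e-12)
        assert score.undersegmentation == 0.0

    def test_transpose_swaps_components(self, toy_table):
        a, b = vi(toy_table), vi(toy_table.transpose())
        assert a.oversegmentation == pytest.approx(b.undersegmentation)
        assert a.undersegmentation == pytest.approx(b.oversegmentation)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="no comparison points"):
            vi(ContingencyTable())

    def test_nonnegative_and_zero_iff_bijection(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            t = random_table(rng)
            score = vi(t)
            assert score.oversegmentation >= 0 and score.undersegmentation >= 0
            bijection = len(t.counts) == len(t.marginal_s()) == len(t.marginal_g())
            if score.total < 1e-12:
                assert bijection
            if not bijection:
                assert score.total > 0


class TestRandIndex:
    def test_identity_is_one(self):
        t = ContingencyTable({(1, 1): 5, (2, 2): 3})
        assert rand_index(t) == 1.0
        assert rand_index(t, adjusted=True) == 1.0

    def test_worked_example(self, toy_table):
        assert rand_index(toy_table) == pytest.approx(24 / 28)

    def test_single_segment_pair(self):
        t = ContingencyTable({(4, 9): 10})
        assert rand_index(t) == 1.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            rand_index(ContingencyTable({(1, 1): 1}))

    def test_adjusted_matches_sklearn(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(13)
        for _ in range(10):
            s = rng.integers(1, 5, size=60)
            g = rng.integers(1, 4, size=60)
            pairs, cnt = np.unique(np.stack([s, g], axis=1), axis=0, return_counts=True)
            t = ContingencyTable({(int(a), int(b)): int(c) for (a, b), c in zip(pairs, cnt)})
            assert rand_index(t, adjusted=True) == pytest.approx(
                adjusted_rand_score(g, s), abs=1e-12
            )


class TestBodyDecompositions:
    def test_identity_all_zero(self):
        t = ContingencyTable({(1, 1): 5, (2, 2): 3})
        assert all(v == 0 for v in body_vi_decomposition(t).values())

    def test_worked_example(self, toy_table):
        d = body_vi_decomposition(toy_table)
        assert d == pytest.approx({1: 0.0, 2: 0.5})

    def test_conservation(self):
        rng = np.random.default_rng(31)
        for _ in range(25):
            t = random_table(rng)
            assert sum(body_vi_decomposition(t).values()) == pytest.approx(
                vi(t).oversegmentation, abs=1e-10
            )
            assert sum(body_vi_decomposition(t.transpose()).values()) == pytest.approx(
                vi(t).undersegmentation, abs=1e-10
            )

    def test_body_under_over_example(self, toy_table):
        over, under = body_under_over(toy_table, 2)
        assert over == pytest.approx(0.5)
        assert under == 0.0  # each test segment is pure

    def test_merge_gives_positive_under(self):
        # S merges both reference bodies into one segment
        t = ContingencyTable({(10, 1): 4, (10, 2): 4})
        over, under = body_under_over(t, 2)
        assert over == 0.0
        assert under == pytest.approx(1.0)  # whole volume, binary entropy 1 bit

    def test_unknown_body_rejected(self, toy_table):
        with pytest.raises(KeyError):
            body_under_over(toy_table, 99)


class TestMatchSegments:
    def test_diagonal_matches_everything(self):
        t = ContingencyTable({(1, 1): 5, (2, 2): 3})
        a = match_segments(t)
        assert a.mapping == {1: 1, 2: 2}

    def test_tiebreak_smaller_test_label(self, toy_table):
        a = match_segments(toy_table)
        assert a.mapping == {1: 10, 2: 20}
        assert a.overlap_weight == {1: 4, 2: 2}

    def test_injective(self):
        t = ContingencyTable({(10, 1): 4, (10, 2): 3})
        a = match_segments(t)
        assert a.mapping == {1: 10}  # test segment 10 cannot serve both

    def test_greedy_le_optimal_weight(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            t = random_table(rng)
            g = match_segments(t, "greedy")
            o = match_segments(t, "optimal")
            assert g.total_weight() <= o.total_weight()

    def test_greedy_equals_optimal_on_split_only(self):
        # every test segment overlaps exactly one reference segment
        t = ContingencyTable({(10, 1): 4, (11, 1): 2, (20, 2): 5, (21, 2): 1})
        g = match_segments(t, "greedy")
        o = match_segments(t, "optimal")
        assert g.total_weight() == o.total_weight()
        assert g.mapping == {1: 10, 2: 20}


class TestConnectionGraph:
    def test_resolution(self):
        data = np.zeros((1, 1, 4), dtype=int)
        data[0, 0, :2] = 1
        data[0, 0, 2:] = 2
        v = LabelVolume(data)
        conns = [
            SynapseConnection(pre=(0, 0, 1), post=(0, 0, 2), id=i) for i in range(3)
        ]
        g = connection_graph(v, conns)
        assert g.weight((1, 2)) == 3
        assert g.unresolved == 0

    def test_background_endpoint_unresolved(self):
        data = np.array([[[1, 0]]])
        v = LabelVolume(data)
        g = connection_graph(v, [SynapseConnection((0, 0, 0), (0, 0, 1), id="a")])
        assert g.n_connections == 0
        assert g.unresolved == 1

    def test_empty_list(self):
        v = LabelVolume(np.ones((1, 1, 1), dtype=int))
        assert connection_graph(v, []).edges == {}

    def test_self_loops_when_one_segment(self):
        v = LabelVolume(np.ones((1, 1, 4), dtype=int))
        g = connection_graph(v, [SynapseConnection((0, 0, 0), (0, 0, 3), id=1)])
        assert g.weight((1, 1)) == 1


class TestConnectivityCorrectness:
    def test_toy_two_thirds(self):
        Sg, Gg, A = make_toy_graphs()
        assert connectivity_correctness(Sg, Gg, A) == pytest.approx(2 / 3)

    def test_perfect_segmentation(self):
        Gg = ConnectionGraph(edges={(1, 2): frozenset({1, 2}), (2, 3): frozenset({3})})
        A = Assignment(mapping={1: 1, 2: 2, 3: 3})
        assert connectivity_correctness(Gg, Gg, A) == 1.0

    def test_false_merge_forfeits_pair(self):
        # bodies 1 and 2 merged into S segment 10; only one can be assigned
        Gg = ConnectionGraph(edges={(1, 2): frozenset({"c1", "c2"})})
        Sg = ConnectionGraph(edges={(10, 10): frozenset({"c1", "c2"})})
        A = Assignment(mapping={1: 10})  # injectivity: body 2 unmatched
        assert connectivity_correctness(Sg, Gg, A) == 0.0

    def test_empty_ground_truth_rejected(self):
        with pytest.raises(ValueError, match="no ground-truth"):
            connectivity_correctness(ConnectionGraph(), ConnectionGraph(), Assignment())


class TestCcThresholded:
    def test_toy_k0(self):
        Sg, Gg, A = make_toy_graphs()
        rec, pre = cc_thresholded(Sg, Gg, A, k=0)
        assert rec == pytest.approx(1.0)
        assert pre == pytest.approx(0.5)

    def test_identity_any_feasible_k(self):
        Gg = ConnectionGraph(edges={(1, 2): frozenset(range(5))})
        A = Assignment(mapping={1: 1, 2: 2})
        for k in range(5):
            rec, pre = cc_thresholded(Gg, Gg, A, k=k)
            assert rec == pre == 1.0

    def test_k_above_all_weights_is_undefined(self):
        Sg, Gg, A = make_toy_graphs()
        rec, pre = cc_thresholded(Sg, Gg, A, k=100)
        assert rec is None and pre is None

    def test_inclusive_flag(self):
        Gg = ConnectionGraph(edges={(1, 2): frozenset(range(10))})
        A = Assignment(mapping={1: 1, 2: 2})
        rec_strict, _ = cc_thresholded(Gg, Gg, A, k=10)
        rec_incl, _ = cc_thresholded(Gg, Gg, A, k=10, inclusive=True)
        assert rec_strict is None  # weight 10 is not > 10
        assert rec_incl == 1.0


class TestFrag:
    def test_identity_zero(self):
        t = ContingencyTable({(1, 1): 5, (2, 2): 3})
        assert frag(t) == 0

    def test_counts_difference(self):
        t = ContingencyTable({(i, 1 + i % 3): 1 for i in range(1, 6)})
        assert frag(t) == 5 - 3

    def test_may_be_negative(self):
        t = ContingencyTable({(1, 1): 2, (1, 2): 2})
        assert frag(t) == -1


class TestFragThresholded:
    def test_single_segment(self):
        assert frag_thresholded({1: 10}, {1: 10}, 50) == (1, 1, 0)

    def test_cumulative_example(self):
        sizes = {1: 50, 2: 30, 3: 10, 4: 5, 5: 5}
        cs, cg, diff = frag_thresholded(sizes, {1: 100}, 75)
        assert cs == 2  # 50 + 30 = 80 >= 75
        assert cg == 1
        assert diff == 1

    def test_hundred_percent_counts_all_nonzero(self):
        sizes = {1: 3, 2: 2, 3: 1}
        cs, _, _ = frag_thresholded(sizes, {1: 1}, 100)
        assert cs == 3

    def test_invalid_percent(self):
        with pytest.raises(ValueError):
            frag_thresholded({1: 1}, {1: 1}, 0)


class TestBodyConnectionCoverage:
    def test_identity_full_coverage(self):
        Gg = ConnectionGraph(edges={(1, 2): frozenset({1, 2}), (2, 3): frozenset({3})})
        A = Assignment(mapping={1: 1, 2: 2, 3: 3})
        cov = body_connection_coverage(Gg, Gg, A)
        assert cov == {1: 1.0, 2: 1.0, 3: 1.0}

    def test_toy_incident_fractions(self):
        Sg, Gg, A = make_toy_graphs()
        cov = body_connection_coverage(Gg, Sg, A)
        assert cov == pytest.approx({1: 2 / 3, 2: 2 / 3})

    def test_unmatched_body_zero(self):
        Gg = ConnectionGraph(edges={(1, 2): frozenset({"x"})})
        Sg = ConnectionGraph(edges={(10, 20): frozenset({"x"})})
        A = Assignment(mapping={1: 99, 2: 98})
        cov = body_connection_coverage(Gg, Sg, A)
        assert cov == {1: 0.0, 2: 0.0}


class TestBestBodies:
    def test_identity_all_one(self):
        t = ContingencyTable({(1, 1): 5, (2, 2): 3})
        assert best_bodies_by_overlap(t) == [(1, 1.0), (2, 1.0)]

    def test_worked_example(self, toy_table):
        ranked = best_bodies_by_overlap(toy_table)
        assert ranked == [(1, 1.0), (2, 0.5)]
        assert ranked[-1][0] == 2  # worst body last


class TestOracleEquivalence:
    def test_vi_and_rand_match_bruteforce_small(self):
        rng = np.random.default_rng(55)
        for _ in range(10):
            S = random_volume(rng, (5, 5, 5), 4)
            G = random_volume(rng, (5, 5, 5), 3)
            t = build_contingency(S, G)
            over, under = brute_vi(S.data, G.data)
            score = vi(t)
            assert score.oversegmentation == pytest.approx(over, abs=1e-10)
            assert score.undersegmentation == pytest.approx(under, abs=1e-10)
            assert rand_index(t) == pytest.approx(brute_rand(S.data, G.data), abs=1e-10)


class TestSubvolumeVi:
    def _blocks(self, volume, grid):
        return {b: extract_block(volume, grid, b) for b in grid.sorted_blocks()}

    def test_identity_all_zero(self):
        rng = np.random.default_rng(6)
        v = random_volume(rng, (8, 8, 8), 4)
        grid = partition_grid(v.bounds, (4, 4, 4))
        scores = subvolume_vi(self._blocks(v, grid), self._blocks(v, grid), grid)
        assert all(s is None or s.total == 0 for s in scores.values())

    def test_corruption_localised_to_one_block(self):
        data = np.ones((8, 8, 8), dtype=int)
        data[:, :4] = 2
        G = LabelVolume(data)
        corrupted = data.copy()
        corrupted[:4, :4, :4][data[:4, :4, :4] == 2] = 7  # split inside block (0,0,0)
        S = LabelVolume(corrupted)
        grid = partition_grid(G.bounds, (4, 4, 4))
        scores = subvolume_vi(self._blocks(S, grid), self._blocks(G, grid), grid)
        nonzero = {b for b, s in scores.items() if s is not None and s.total > 0}
        assert nonzero == set()  # the cut coincides with the block boundary: no local error

        corrupted2 = data.copy()
        corrupted2[:2, :4, :4][data[:2, :4, :4] == 2] = 7  # cut interior to the block
        scores2 = subvolume_vi(
            self._blocks(LabelVolume(corrupted2), grid), self._blocks(G, grid), grid
        )
        nonzero2 = {b for b, s in scores2.items() if s is not None and s.total > 0}
        assert nonzero2 == {(0, 0, 0)}

    def test_single_block_consistency(self):
        rng = np.random.default_rng(23)
        S = random_volume(rng, (6, 6, 6), 4)
        G = random_volume(rng, (6, 6, 6), 3)
        grid = partition_grid(S.bounds, (6, 6, 6))
        from conneval.preprocess import local_connected_components

        s_local, _ = local_connected_components(S)
        g_local, _ = local_connected_components(G)
        expected = vi(build_contingency(s_local, g_local))
        got = subvolume_vi({(0, 0, 0): S}, {(0, 0, 0): G}, grid)[(0, 0, 0)]
        assert got.total == pytest.approx(expected.total, abs=1e-12)
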