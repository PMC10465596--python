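"""Dotprops, NBLAST, flow centrality and segregation-index behaviour."""

import numpy as np
import pytest

from glomnet import (
    DotProps,
    ParametricScoring,
    TableScoring,
    flow_centrality,
    nblast,
    nblast_mean,
    segregation_index,
    to_dotprops,
)
from glomnet.model import InputError, Skeleton
from glomnet.morphometry import _resample_polyline


def line_skeleton(n, step=1000.0, axis=0):
    xyz = np.zeros((n, 3))
    xyz[:, axis] = np.arange(n) * step
    return Skeleton("line", np.arange(1, n + 1),
                    np.concatenate([[-1], np.arange(1, n)]), xyz, np.ones(n))


def random_tree(n_nodes, rng, scale=2000.0):
    parents = [-1] + [int(rng.integers(1, i + 1)) for i in range(1, n_nodes)]
    xyz = rng.normal(scale=scale, size=(n_nodes, 3))
    return Skeleton("t", np.arange(1, n_nodes + 1), np.array(parents),
                    xyz, np.ones(n_nodes))


def brute_force_flow(sk, inputs, outputs):
    """Oracle: per node v, count input->output pairs separated by v's subtree.

    A pair contributes to C(v) when exactly one endpoint lies at-or-distal to
    v — equivalently, its tree path traverses the edge between v and its
    parent. Subtree membership comes from networkx descendants, fully
    independent of the implementation's subtree accumulation.
    """
    import networkx as nx
    g = nx.DiGraph()
    for n, p in zip(sk.node_ids, sk.parent_ids):
        if p != -1:
            g.add_edge(int(p), int(n))
    g.add_nodes_from(int(n) for n in sk.node_ids)
    counts = {}
    for v in (int(n) for n in sk.node_ids):
        subtree = nx.descendants(g, v) | {v}
        counts[v] = sum((int(i) in subtree) != (int(o) in subtree)
                        for i in inputs for o in outputs)
    return counts


class TestDotProps:
    def test_straight_segment_tangents_along_x(self):
        dp = to_dotprops(line_skeleton(3), spacing=500.0)
        assert np.allclose(np.abs(dp.tangents[:, 0]), 1.0, atol=1e-6)

    def test_resampled_point_count_tracks_cable_length(self):
        # 100 um cable at 1 um spacing
        sk = line_skeleton(21, step=5000.0)
        dp = to_dotprops(sk, spacing=1000.0)
        assert 90 <= len(dp) <= 110

    def test_deterministic(self, small_population):
        cn, truth, _ = small_population
        sk = cn.skeletons[truth.patchy_ids[0]]
        a, b = to_dotprops(sk), to_dotprops(sk)
        np.testing.assert_array_equal(a.points, b.points)
        np.testing.assert_array_equal(a.tangents, b.tangents)

    def test_single_node_flagged(self):
        sk = Skeleton("pt", [1], [-1], np.zeros((1, 3)), np.ones(1))
        dp = to_dotprops(sk)
        assert dp.single_point and len(dp) == 1

    def test_unit_tangent_invariant_enforced(self):
        with pytest.raises(InputError):
            DotProps("x", np.zeros((1, 3)), np.array([[2.0, 0.0, 0.0]]))

    def test_resample_polyline_spacing(self):
        line = np.column_stack([np.linspace(0, 10_000, 5), np.zeros(5), np.zeros(5)])
        pts = _resample_polyline(line, 1000.0)
        assert len(pts) == 11


class TestNblast:
    def test_self_score_is_exactly_one_both_scorings(self, rng):
        pts = rng.normal(scale=3000.0, size=(40, 3))
        tg = rng.normal(size=(40, 3))
        tg /= np.linalg.norm(tg, axis=1, keepdims=True)
        dp = DotProps("a", pts, tg)
        table = TableScoring(
            d_edges=np.array([0.0, 1000.0, 5000.0, 1e7]),
            dot_edges=np.array([0.0, 0.5, 1.0]),
            values=np.array([[1.0, 4.0], [0.0, 1.0], [-5.0, -5.0]]),
        )
        assert nblast(dp, dp).normalized == 1.0
        assert nblast(dp, dp, scoring=table).normalized == 1.0

    def test_distant_clouds_hit_table_minimum(self, rng):
        pts = rng.normal(scale=1000.0, size=(20, 3))
        tg = np.tile([1.0, 0.0, 0.0], (20, 1))
        a = DotProps("a", pts, tg)
        b = DotProps("b", pts + 1e6, tg)
        table = TableScoring(
            d_edges=np.array([0.0, 1000.0, 5000.0, 1e5]),
            dot_edges=np.array([0.0, 1.0]),
            values=np.array([[4.0], [1.0], [-5.0]]),
        )
        score = nblast(a, b, scoring=table)
        assert score.raw == pytest.approx(20 * -5.0)
        assert score.normalized < 0

    def test_three_point_parametric_matches_hand_sum(self):
        qp = np.array([[0.0, 0, 0], [1000.0, 0, 0], [2000.0, 0, 0]])
        tp = np.array([[0.0, 500.0, 0], [1000.0, 500.0, 0], [3000.0, 0, 0]])
        tgq = np.tile([1.0, 0, 0], (3, 1))
        tgt = np.vstack([[1.0, 0, 0], [0.0, 1.0, 0], [1.0, 0, 0]])
        q, t = DotProps("q", qp, tgq), DotProps("t", tp, tgt)
        # brute force over the 3x3 distance matrix
        expected = 0.0
        for i in range(3):
            d = np.linalg.norm(tp - qp[i], axis=1)
            j = np.argmin(d)
            expected += np.exp(-d[j] / 3000.0) * abs(np.dot(tgq[i], tgt[j]))
        assert nblast(q, t).raw == pytest.approx(expected, rel=1e-12)

    def test_point_order_permutation_invariance(self, rng):
        pts = rng.normal(scale=2000.0, size=(30, 3))
        tg = rng.normal(size=(30, 3))
        tg /= np.linalg.norm(tg, axis=1, keepdims=True)
        tpts = rng.normal(scale=2000.0, size=(25, 3))
        ttg = rng.normal(size=(25, 3))
        ttg /= np.linalg.norm(ttg, axis=1, keepdims=True)
        perm = rng.permutation(30)
        a = nblast(DotProps("a", pts, tg), DotProps("b", tpts, ttg))
        b = nblast(DotProps("a", pts[perm], tg[perm]), DotProps("b", tpts, ttg))
        assert a.raw == pytest.approx(b.raw, rel=1e-12)

    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation
        pts = rng.normal(scale=2000.0, size=(30, 3))
        tg = rng.normal(size=(30, 3))
        tg /= np.linalg.norm(tg, axis=1, keepdims=True)
        tpts = pts + rng.normal(scale=500.0, size=pts.shape)
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        t = np.array([1e4, -2e4, 3e3])
        before = nblast_mean(DotProps("a", pts, tg), DotProps("b", tpts, tg))
        after = nblast_mean(
            DotProps("a", pts @ R.T + t, tg @ R.T),
            DotProps("b", tpts @ R.T + t, tg @ R.T))
        assert after == pytest.approx(before, rel=1e-9)

    def test_too_few_neighbours_rejected(self):
        with pytest.raises(InputError):
            to_dotprops(line_skeleton(5), k=1)

    def test_table_csv_round_trip(self, tmp_path):
        table = TableScoring(
            d_edges=np.array([0.0, 1000.0, 5000.0]),
            dot_edges=np.array([0.0, 0.5, 1.0]),
            values=np.array([[1.0, 4.0], [-1.0, 0.5]]),
        )
        table.to_csv(tmp_path / "smat.csv")
        back = TableScoring.from_csv(tmp_path / "smat.csv")
        np.testing.assert_allclose(back.d_edges, table.d_edges)
        np.testing.assert_allclose(back.dot_edges, table.dot_edges)
        np.testing.assert_allclose(back.values, table.values)
        assert back(np.array([1200.0]), np.array([0.7]))[0] == 0.5


class TestFlowCentrality:
    def test_path_graph_worked_example(self):
        sk = line_skeleton(5)
        split = flow_centrality(sk, [1, 2], [4, 5])
        c = dict(zip(split.node_ids, split.total))
        assert c[3] == 4 and max(c.values()) == 4
        assert split.split_node == 3
        assert split.segregation == pytest.approx(1.0)
        # inputs proximal -> dendrite side holds nodes 1-2
        assert split.compartment[1] == "dendrite"
        assert split.compartment[5] == "axon"

    def test_outputs_only_is_degenerate(self):
        sk = line_skeleton(4)
        split = flow_centrality(sk, [], [3, 4])
        assert split.degenerate
        assert np.all(split.total == 0)

    def test_unknown_site_rejected(self):
        with pytest.raises(Exception, match="99"):
            flow_centrality(line_skeleton(4), [99], [2])

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_pair_path_oracle_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 51))
        sk = random_tree(n, rng)
        sites = rng.integers(1, n + 1, size=20)
        inputs, outputs = list(sites[:10]), list(sites[10:])
        split = flow_centrality(sk, inputs, outputs)
        oracle = brute_force_flow(sk, inputs, outputs)
        for node, c in zip(split.node_ids, split.total):
            assert c == oracle[int(node)], f"node {node}"


class TestSegregationIndex:
    def test_fully_segregated_is_one(self):
        assert segregation_index([(5, 0), (0, 7)]) == pytest.approx(1.0)

    def test_fully_mixed_is_zero(self):
        assert segregation_index([(4, 4), (2, 2)]) == pytest.approx(0.0)

    def test_worked_entropy_case(self):
        s = segregation_index([(3, 1), (1, 3)])
        h = lambda p: -p * np.log(p) - (1 - p) * np.log(1 - p)
        assert s == pytest.approx(1 - h(0.75) / h(0.5), abs=1e-12)
        assert s == pytest.approx(0.1887, abs=2e-4)

    def test_label_swap_invariance(self, rng):
        for _ in range(20):
            comp = [(int(rng.integers(0, 9)), int(rng.integers(0, 9)))
                    for _ in range(3)]
            if sum(i + o for i, o in comp) == 0:
                continue
            swapped = [(o, i) for i, o in comp]
            assert segregation_index(comp) == pytest.approx(
                segregation_index(swapped), abs=1e-12)

    def test_all_empty_rejected(self):
        with pytest.raises(InputError):
            segregation_index([(0, 0)])

    def test_pure_pool_convention_zero(self):
        assert segregation_index([(3, 0), (2, 0)]) == 0.0
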