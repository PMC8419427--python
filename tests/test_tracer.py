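import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from caatrace.io_formats import Volume
from caatrace.probmap import initial_segmentation
from caatrace.tracer import (
    TraceNode,
    TracingParams,
    VoxelCluster,
    caat_search,
    connectivity_score,
    continuity_probability,
    distance_score,
    dpc_score,
    line_voxels,
    scoop_step,
    scooping_distance,
    trace_all,
)

from conftest import make_tube_prob, segmentation_from_mask

voxels = st.tuples(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20))


def node_at(center, cluster_voxels, radius=1.0, comp=1):
    return TraceNode(0, tuple(float(c) for c in center), radius, -1,
                     VoxelCluster(frozenset(cluster_voxels), component_id=comp))


class TestDistanceScore:
    def test_inside_dt_full_score(self):
        d, s = distance_score((0, 0, 0), (1, 2, 3), d_t=4)
        assert (d, s) == (3.0, 1.0)

    def test_boundary_inclusive(self):
        d, s = distance_score((0, 0, 0), (0, 0, 4), d_t=4)
        assert (d, s) == (4.0, 1.0)

    def test_exponential_decay_beyond_dt(self):
        d, s = distance_score((0, 0, 0), (1, 2, 7), d_t=4)
        assert d == 7.0
        assert s == pytest.approx(math.exp(-1.0), rel=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(voxels, voxels)
    def test_matches_chebyshev_and_range(self, a, b):
        d, s = distance_score(a, b, d_t=5)
        assert d == max(abs(x - y) for x, y in zip(a, b))
        assert 0.0 < s <= 1.0
        # continuity at the boundary
        if d > 5:
            assert s == pytest.approx(math.exp(-(d - 5) / 3.0), rel=1e-12)


class TestConnectivityScore:
    def test_same_component_blocked(self):
        assert connectivity_score(5, 5) == 0.0

    def test_different_components_pass(self):
        assert connectivity_score(5, 7) == 1.0

    def test_symmetric(self):
        assert connectivity_score(3, 9) == connectivity_score(9, 3)


class TestLineVoxels:
    def test_adjacent_voxels_empty_chain(self):
        assert line_voxels((0, 0, 0), (1, 1, 1)) == []

    def test_axis_line(self):
        chain = line_voxels((0, 0, 0), (0, 0, 5))
        assert chain == [(0, 0, 1), (0, 0, 2), (0, 0, 3), (0, 0, 4)]

    def test_identical_endpoints_rejected(self):
        with pytest.raises(ValueError):
            line_voxels((1, 1, 1), (1, 1, 1))

    @settings(max_examples=150, derandomize=True)
    @given(voxels, voxels)
    def test_chain_is_26_connected_and_monotone(self, a, b):
        if a == b:
            return
        chain = [a] + line_voxels(a, b) + [b]
        assert len(chain) == max(abs(x - y) for x, y in zip(a, b)) + 1
        for u, v in zip(chain, chain[1:]):
            step = [v[i] - u[i] for i in range(3)]
            assert max(abs(s) for s in step) == 1  # 26-connected, no repeats
            for i in range(3):  # monotone toward b
                assert step[i] * np.sign(b[i] - a[i]) >= 0

    @settings(max_examples=150, derandomize=True)
    @given(voxels, voxels)
    def test_symmetric_rasterization(self, a, b):
        if a == b:
            return
        assert line_voxels(a, b) == line_voxels(b, a)[::-1]


class TestContinuityProbability:
    def test_above_threshold_full_credit(self):
        assert continuity_probability(0.5, 0.1) == 1.0

    def test_below_threshold_identity(self):
        assert continuity_probability(0.05, 0.1) == 0.05

    def test_boundary_goes_to_identity(self):
        assert continuity_probability(0.1, 0.1) == 0.1


class TestDpcScore:
    def _corridor(self, values):
        arr = np.zeros((3, 3, 12))
        arr[1, 1, 1:11] = values
        return Volume(arr, kind="probability")

    def test_perfect_corridor(self):
        prob = self._corridor(0.5)
        assert dpc_score((1, 1, 0), (1, 1, 11), prob, t_l=0.1) == pytest.approx(1.0)

    def test_dead_corridor(self):
        prob = self._corridor(0.0)
        assert dpc_score((1, 1, 0), (1, 1, 11), prob, t_l=0.1) == pytest.approx(
            math.exp(-1.0), rel=1e-12
        )

    def test_half_alive_corridor(self):
        arr = np.zeros((3, 3, 12))
        arr[1, 1, 1:6] = 0.5  # 5 of the 10 interior voxels above t_l
        prob = Volume(arr, kind="probability")
        assert dpc_score((1, 1, 0), (1, 1, 11), prob, t_l=0.1) == pytest.approx(
            math.exp(-0.5), rel=1e-12
        )

    def test_adjacent_pair_scores_one(self):
        prob = self._corridor(0.0)
        assert dpc_score((1, 1, 0), (1, 1, 1), prob, t_l=0.1) == 1.0


class TestScooping:
    def test_isolated_frontier_distance_zero(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        seg = segmentation_from_mask(mask)
        visited = mask.copy()
        node = node_at((2, 2, 2), [(2, 2, 2)])
        assert scooping_distance(node, node.cluster, visited, seg) == 0.0

    def test_single_neighbor_distance_one(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2:4] = True
        seg = segmentation_from_mask(mask)
        visited = np.zeros_like(mask)
        visited[2, 2, 2] = True
        node = node_at((2, 2, 2), [(2, 2, 2)])
        assert scooping_distance(node, node.cluster, visited, seg) == 1.0

    def test_diagonal_neighbor_matches_brute_force(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        mask[3, 3, 3] = True
        seg = segmentation_from_mask(mask)
        visited = np.zeros_like(mask)
        visited[2, 2, 2] = True
        node = node_at((1.5, 2.0, 2.0), [(2, 2, 2)])
        expected = math.dist((1.5, 2.0, 2.0), (3, 3, 3))
        assert scooping_distance(node, node.cluster, visited, seg) == pytest.approx(expected)

    def test_line_advances_one_cluster_per_step(self):
        mask = np.zeros((3, 3, 20), dtype=bool)
        mask[1, 1, :] = True
        seg = segmentation_from_mask(mask)
        visited = np.zeros_like(mask)
        visited[1, 1, 0] = True
        node = node_at((1, 1, 0), [(1, 1, 0)])
        frontier = node.cluster
        reached = 0
        for _ in range(25):
            clusters = scoop_step(node, frontier, visited, seg)
            if not clusters:
                break
            assert len(clusters) == 1
            new_x = max(v[2] for v in clusters[0].voxels)
            assert new_x >= reached + 1
            reached = new_x
            node = node_at(clusters[0].centroid(), clusters[0].voxels)
            frontier = clusters[0]
        assert reached == 19

    def test_y_junction_splits_into_two_clusters(self):
        mask = np.zeros((11, 11, 11), dtype=bool)
        for x in range(5):
            mask[5, 5, x] = True  # stem
        for k in range(1, 4):
            mask[5, 5 + k, 4 + k] = True  # upper arm
            mask[5, 5 - k, 4 + k] = True  # lower arm
        seg = segmentation_from_mask(mask)
        visited = np.zeros_like(mask)
        for x in range(5):
            visited[5, 5, x] = True
        node = node_at((5, 5, 3), [(5, 5, 4)])
        clusters = scoop_step(node, node.cluster, visited, seg)
        assert len(clusters) == 2

    def test_fully_visited_returns_empty(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1, 1, 1:3] = True
        seg = segmentation_from_mask(mask)
        visited = mask.copy()
        node = node_at((1, 1, 1), [(1, 1, 1)])
        assert scoop_step(node, node.cluster, visited, seg) == []


class TestCaatSearch:
    def _two_fragment_setup(self, gap, corridor_level, shape=(7, 7, 30)):
        """Two coaxial 1-voxel line fragments with `gap` voxels between ends."""
        mask = np.zeros(shape, dtype=bool)
        mask[3, 3, 0:10] = True
        mask[3, 3, 9 + gap:9 + gap + 10] = True
        prob = np.zeros(shape)
        prob[mask] = 0.9
        prob[3, 3, 10:9 + gap] = corridor_level
        seg = segmentation_from_mask(mask)
        visited = np.zeros_like(mask)
        visited[3, 3, 0:10] = True
        node = node_at((3, 3, 9), [(3, 3, 9)])
        return node, seg, Volume(prob, kind="probability"), visited

    def test_no_candidate_in_window(self):
        node, seg, prob, visited = self._two_fragment_setup(gap=25, corridor_level=0.0, shape=(7, 7, 50))
        params = TracingParams(d_t=5, t_l=0.1)
        assert caat_search(node, node.cluster, seg, prob, visited, params) is None

    def test_short_gap_with_live_corridor_bridged(self):
        node, seg, prob, visited = self._two_fragment_setup(gap=3, corridor_level=0.5)
        params = TracingParams(d_t=5, t_l=0.1)
        la = caat_search(node, node.cluster, seg, prob, visited, params)
        assert la is not None
        assert la.d == 3.0
        assert la.d_score == 1.0 and la.c_score == 1.0
        assert la.dpc_score == pytest.approx(1.0)
        assert la.link_score == pytest.approx(1.0)
        assert la.s_p == (3, 3, 12)

    def test_same_component_never_linked(self):
        # unvisited voxels ahead belong to the frontier's own component
        mask = np.zeros((7, 7, 30), dtype=bool)
        mask[3, 3, 0:20] = True
        prob = np.where(mask, 0.9, 0.0)
        seg = segmentation_from_mask(mask)
        visited = np.zeros_like(mask)
        visited[3, 3, 0:10] = True
        node = node_at((3, 3, 9), [(3, 3, 9)])
        params = TracingParams(d_t=5, t_l=0.1)
        assert caat_search(node, node.cluster, seg, Volume(prob, kind="probability"), visited, params) is None

    def test_link_score_is_exact_product(self):
        node, seg, prob, visited = self._two_fragment_setup(gap=7, corridor_level=0.5)
        params = TracingParams(d_t=5, t_l=0.1)
        la = caat_search(node, node.cluster, seg, prob, visited, params)
        assert la is not None
        assert la.link_score == la.d_score * la.c_score * la.dpc_score
        assert 0 <= la.d_score <= 1 and la.c_score in (0.0, 1.0) and 0 <= la.dpc_score <= 1

    @pytest.mark.parametrize("gap, expect_link", [(7, True), (8, False)])
    def test_feasibility_bound_with_perfect_corridor(self, gap, expect_link):
        # with dpc = c = 1 a gap bridges iff d <= d_t + 3 ln 2
        node, seg, prob, visited = self._two_fragment_setup(gap=gap, corridor_level=0.5)
        params = TracingParams(d_t=5, t_l=0.1)
        la = caat_search(node, node.cluster, seg, prob, visited, params)
        assert (la is not None) == expect_link


class TestTraceAll:
    def test_unbroken_tube_single_accurate_graph(self):
        prob, gold = make_tube_prob()
        seg = initial_segmentation(prob)
        graphs = trace_all(prob, seg, TracingParams())
        assert len(graphs) == 1
        centers = np.array([n.center for n in graphs[0].nodes.values()])
        from scipy.spatial import cKDTree

        d, _ = cKDTree(gold).query(centers)
        assert d.max() <= 1.5

    def test_gap_bridged_consumes_both_seeds(self):
        prob, _ = make_tube_prob(gap=(40, 4), gap_level=0.05)
        seg = initial_segmentation(prob)
        assert seg.n_components == 2
        graphs = trace_all(prob, seg, TracingParams(d_t=5))
        assert len(graphs) == 1
        assert len(graphs[0].links) == 1
        assert graphs[0].components == {1, 2}

    def test_parallel_tubes_stay_separate(self):
        shape = (32, 32, 60)
        zz, yy, xx = np.indices(shape)
        m1 = ((zz - 16) ** 2 + (yy - 6) ** 2 <= 4) & (xx >= 4) & (xx <= 55)
        m2 = ((zz - 16) ** 2 + (yy - 26) ** 2 <= 4) & (xx >= 4) & (xx <= 55)
        rng = np.random.default_rng(0)
        prob = np.minimum(np.abs(rng.normal(0, 0.03, shape)), 0.06)
        prob[m1 | m2] = 0.9
        vol = Volume(np.clip(prob, 0, 1), kind="probability")
        seg = initial_segmentation(vol)
        graphs = trace_all(vol, seg, TracingParams(d_t=5))
        assert len(graphs) == 2
        assert all(not g.links for g in graphs)

    def test_conservation_and_acyclicity(self):
        prob, _ = make_tube_prob(gap=(40, 4), gap_level=0.05)
        seg = initial_segmentation(prob)
        graphs = trace_all(prob, seg, TracingParams())
        fg = set(map(tuple, np.argwhere(seg.labels.values > 0)))
        seen = set()
        for g in graphs:
            assert len(g.nodes) >= 1
            n_edges = sum(1 for n in g.nodes.values() if n.parent_id != -1)
            assert n_edges == len(g.nodes) - 1  # tree
            for n in g.nodes.values():
                for v in n.cluster.voxels:
                    assert v not in seen  # visited at most once
                    seen.add(v)
                    assert v in fg

    def test_empty_segmentation_empty_forest(self):
        arr = np.full((6, 6, 6), 0.1)
        vol = Volume(arr, kind="probability")
        with pytest.warns(UserWarning):
            seg = initial_segmentation(vol)
        assert trace_all(vol, seg, TracingParams()) == []

    def test_determinism_two_runs_identical(self):
        prob, _ = make_tube_prob(gap=(40, 4), gap_level=0.05)
        seg1 = initial_segmentation(prob)
        seg2 = initial_segmentation(prob)
        g1 = trace_all(prob, seg1, TracingParams())
        g2 = trace_all(prob, seg2, TracingParams())
        c1 = [n.center for g in g1 for n in g.nodes.values()]
        c2 = [n.center for g in g2 for n in g.nodes.values()]
        assert c1 == c2
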