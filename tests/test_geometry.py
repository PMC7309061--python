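"""Geometric primitives against brute-force / closed-form oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nits.geometry import (
    SpiralSpec,
    discrete_frechet,
    generate_spiral,
    neighbor_matching_similarity,
    parallel_angle,
    parallel_pairs_score,
    percentage_match,
    resolve_stroke_nodes,
)
from nits.session_io import graph_layout, TouchEvent, TouchTrajectory


# ---------------------------------------------------------------------------
# Independent oracles


def frechet_bruteforce(a, b):
    """Minimax over all monotone couplings, by memoized recursion."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def go(i, j):
        d = float(np.linalg.norm(a[i] - b[j]))
        if i == 0 and j == 0:
            return d
        opts = []
        if i > 0:
            opts.append(go(i - 1, j))
        if j > 0:
            opts.append(go(i, j - 1))
        if i > 0 and j > 0:
            opts.append(go(i - 1, j - 1))
        return max(d, min(opts))

    return go(len(a) - 1, len(b) - 1)


def neighbor_matching_oracle(adj1, adj2, eps=1e-6, max_iter=2000):
    """Fixed-point neighbor matching with permutation-enumerated assignment."""
    ids1, ids2 = sorted(adj1), sorted(adj2)
    sim = {(i, j): 1.0 for i in ids1 for j in ids2}
    for _ in range(max_iter):
        new = {}
        for i in ids1:
            for j in ids2:
                a, b = sorted(adj1[i]), sorted(adj2[j])
                if not a and not b:
                    new[i, j] = 1.0
                    continue
                if not a or not b:
                    new[i, j] = 0.0
                    continue
                small, large, swap = (a, b, False) if len(a) <= len(b) else (b, a, True)
                best = 0.0
                for perm in itertools.permutations(large, len(small)):
                    tot = 0.0
                    for u, v in zip(small, perm):
                        tot += sim[(v, u) if swap else (u, v)] if not swap else sim[v, u]
                    best = max(best, tot)
                new[i, j] = best / max(len(a), len(b))
        delta = max(abs(new[k] - sim[k]) for k in sim)
        sim = new
        if delta < eps:
            break
    # optimal full assignment by enumeration
    small, large, swap = (ids1, ids2, False) if len(ids1) <= len(ids2) else (ids2, ids1, True)
    best = 0.0
    for perm in itertools.permutations(large, len(small)):
        tot = sum(sim[(v, u) if swap else (u, v)] for u, v in zip(small, perm))
        best = max(best, tot)
    return best / max(len(ids1), len(ids2))


# ---------------------------------------------------------------------------
# Spiral


class TestSpiral:
    def test_outer_radius_equals_spacing_times_turns(self):
        c = generate_spiral(SpiralSpec(spacing_px=10.0, turns=1.0, n_points=5))
        assert np.linalg.norm(c[-1]) == pytest.approx(10.0)
        assert np.allclose(c[0], (0.0, 0.0))

    def test_cw_ccw_mirror_symmetry(self):
        cw = generate_spiral(SpiralSpec(spacing_px=10.0, turns=2.0, n_points=64))
        ccw = generate_spiral(SpiralSpec(spacing_px=10.0, turns=2.0, n_points=64,
                                         direction="ccw"))
        np.testing.assert_allclose(ccw[:, 0], -cw[:, 0])
        np.testing.assert_allclose(ccw[:, 1], cw[:, 1])

    def test_arc_length_monotone(self):
        c = generate_spiral(SpiralSpec(spacing_px=20.0, turns=3.0, n_points=256))
        seg = np.linalg.norm(np.diff(c, axis=0), axis=1)
        s = np.cumsum(seg)
        assert np.all(np.diff(s) > 0)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SpiralSpec(spacing_px=-1.0)
        with pytest.raises(ValueError):
            SpiralSpec(turns=0.0)


# ---------------------------------------------------------------------------
# Discrete Frechet


class TestDiscreteFrechet:
    def test_identical_curves_zero(self):
        c = [(0, 0), (1, 2), (3, 1)]
        assert discrete_frechet(c, c) == 0.0

    def test_uniform_offset(self):
        assert discrete_frechet([(0, 0), (1, 0)], [(0, 1), (1, 1)]) == pytest.approx(1.0)

    def test_detour_curve(self):
        got = discrete_frechet([(0, 0), (4, 0)], [(0, 0), (2, 3), (4, 0)])
        assert got == pytest.approx(np.sqrt(13.0))
        assert got == pytest.approx(frechet_bruteforce([(0, 0), (4, 0)],
                                                       [(0, 0), (2, 3), (4, 0)]))

    def test_matches_bruteforce_on_random_small_curves(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            a = rng.uniform(-5, 5, size=(rng.integers(1, 8), 2))
            b = rng.uniform(-5, 5, size=(rng.integers(1, 8), 2))
            assert discrete_frechet(a, b) == pytest.approx(frechet_bruteforce(a, b))

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            a, b, c = (rng.uniform(-3, 3, size=(rng.integers(2, 8), 2)) for _ in range(3))
            dab = discrete_frechet(a, b)
            dba = discrete_frechet(b, a)
            assert dab == pytest.approx(dba)  # symmetry
            assert dab + discrete_frechet(b, c) >= discrete_frechet(a, c) - 1e-9

    @given(st.lists(st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
                    min_size=1, max_size=7),
           st.tuples(st.floats(-50, 50), st.floats(-50, 50)))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_constant_offset_gives_offset_norm(self, pts, v):
        a = np.asarray(pts, float)
        b = a + np.asarray(v, float)
        assert discrete_frechet(a, b) == pytest.approx(float(np.hypot(*v)), abs=1e-9)

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            discrete_frechet(np.empty((0, 2)), [(0, 0)])


# ---------------------------------------------------------------------------
# Percentage match


class TestPercentageMatch:
    def test_identical_is_one(self):
        c = np.array([(0, 0), (1, 1), (2, 0)], float)
        assert percentage_match(c, c, radius_px=0.5) == 1.0

    def test_all_far_is_zero(self):
        drawn = np.array([(100, 100), (101, 100)], float)
        ref = np.array([(0, 0), (1, 0)], float)
        assert percentage_match(drawn, ref, radius_px=5.0) == 0.0

    def test_partial_count(self):
        ref = np.array([(0, 0)], float)
        drawn = np.array([(0, 0.5), (0.5, 0), (0, -0.9), (5, 5)], float)
        assert percentage_match(drawn, ref, radius_px=1.0) == pytest.approx(0.75)

    def test_reorder_invariant_and_monotone_in_radius(self):
        rng = np.random.default_rng(2)
        ref = rng.uniform(0, 10, size=(20, 2))
        drawn = rng.uniform(0, 10, size=(15, 2))
        shuffled = drawn[rng.permutation(15)]
        prev = 0.0
        for r in (0.5, 1.0, 2.0, 4.0, 8.0):
            m = percentage_match(drawn, ref, r)
            assert m == percentage_match(shuffled, ref, r)
            assert m >= prev
            prev = m


# ---------------------------------------------------------------------------
# Parallel angles


class TestParallelAngles:
    @pytest.mark.parametrize("m1,m2,expected", [
        (2.0, 2.0, 0.0), (0.0, 1.0, 45.0), (1.0, -1.0, 90.0),
        (None, None, 0.0), (0.0, 0.0, 0.0),
    ])
    def test_angles(self, m1, m2, expected):
        assert parallel_angle(m1, m2) == pytest.approx(expected)

    def test_pairs_score_all_parallel(self):
        slopes = [1.0, 1.0, 1.0]
        frac, ok = parallel_pairs_score(slopes, [(0, 1), (1, 2), (0, 2)])
        assert frac == 1.0 and ok

    def test_pairs_score_none_within_tolerance(self):
        slopes = [0.0, 1.0]
        frac, ok = parallel_pairs_score(slopes, [(0, 1)] * 9)
        assert frac == 0.0 and not ok

    def test_pairs_score_five_of_nine_passes(self):
        slopes = [0.0, 0.05, 5.0]
        pairs = [(0, 1)] * 5 + [(0, 2)] * 4  # 5 near-parallel, 4 not
        frac, ok = parallel_pairs_score(slopes, pairs)
        assert frac == pytest.approx(5 / 9)
        assert ok

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            parallel_pairs_score([0.0], [])


# ---------------------------------------------------------------------------
# Node-hit resolution


def _stroke(points):
    return TouchTrajectory(events=tuple(
        TouchEvent(t_ms=i * 10, x_px=float(x), y_px=float(y))
        for i, (x, y) in enumerate(points)))


class TestResolveStrokeNodes:
    layout = graph_layout([("a", 0, 0), ("b", 100, 0), ("c", 50, 80)],
                          node_radius_px=10.0)

    def test_straight_stroke_hits_both_endpoints(self):
        stroke = _stroke(np.linspace((0, 0), (100, 0), 20))
        assert resolve_stroke_nodes(stroke, self.layout) == ["a", "b"]

    def test_far_stroke_hits_nothing(self):
        stroke = _stroke([(300, 300), (400, 300)])
        assert resolve_stroke_nodes(stroke, self.layout) == []

    def test_grazing_three_nodes_in_touch_order(self):
        pts = list(np.linspace((0, 0), (50, 80), 15)) + list(np.linspace((50, 80), (100, 0), 15))
        assert resolve_stroke_nodes(_stroke(pts), self.layout) == ["a", "c", "b"]


# ---------------------------------------------------------------------------
# Neighbor matching


class TestNeighborMatching:
    def test_identical_graphs_score_one(self):
        g = graph_layout([("a", 0, 0), ("b", 1, 0), ("c", 0, 1)],
                         edges=[("a", "b"), ("b", "c")])
        assert neighbor_matching_similarity(g, g) == pytest.approx(1.0)

    def test_isomorphic_relabeling_scores_one(self):
        g1 = {"a": {"b"}, "b": {"a", "c"}, "c": {"b"}}
        g2 = {"x": {"y"}, "y": {"x", "z"}, "z": {"y"}}
        assert neighbor_matching_similarity(g1, g2) == pytest.approx(1.0)

    def test_matches_fixed_point_oracle(self):
        path3 = {"a": {"b"}, "b": {"a", "c"}, "c": {"b"}}
        cycle3 = {"x": {"y", "z"}, "y": {"x", "z"}, "z": {"x", "y"}}
        star4 = {"h": {"p", "q", "r"}, "p": {"h"}, "q": {"h"}, "r": {"h"}}
        path4 = {"a": {"b"}, "b": {"a", "c"}, "c": {"b", "d"}, "d": {"c"}}
        for g1, g2 in [(path3, cycle3), (star4, path4), (path3, path4), (star4, cycle3)]:
            got = neighbor_matching_similarity(g1, g2, eps=1e-6)
            want = neighbor_matching_oracle(g1, g2, eps=1e-6)
            assert got == pytest.approx(want, abs=1e-3)

    def test_symmetric_in_arguments(self):
        g1 = {"a": {"b"}, "b": {"a", "c"}, "c": {"b"}}
        g2 = {"x": {"y", "z"}, "y": {"x", "z"}, "z": {"x", "y"}}
        assert neighbor_matching_similarity(g1, g2) == pytest.approx(
            neighbor_matching_similarity(g2, g1))

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            neighbor_matching_similarity({}, {"a": set()})
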