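"""Skeleton-graph construction: pixel classes, junction clusters, tracing."""

import math

import numpy as np
import pytest

from retvasc.graph import (
    EXTREMITY,
    NODE,
    SLAB,
    build_skeleton_graph,
    classify_pixels,
    cluster_junctions,
    cycle_rank,
    prune_spurs,
    trace_edges,
)
from retvasc.synthetic import VascularTreeSpec, generate_topology

from conftest import DIAG3, H_SHAPE, LINE5, PLUS_SYMMETRIC, RING, THETA, raster

SQRT2 = math.sqrt(2.0)


class TestClassifyPixels:
    def test_five_pixel_line(self):
        cm = classify_pixels(LINE5)
        assert (cm == EXTREMITY).sum() == 2
        assert (cm == SLAB).sum() == 3
        assert (cm == NODE).sum() == 0

    def test_plus_sign(self):
        # center has 4 neighbors; by the >=3-neighbor rule the four arm
        # pixels touching it also count 4 neighbors each (diagonal
        # adjacency between arms), so the junction cluster has 5 node px
        cm = classify_pixels(PLUS_SYMMETRIC)
        assert (cm == NODE).sum() == 5
        assert (cm == EXTREMITY).sum() == 4
        assert cm[3, 3] == NODE

    def test_closed_ring_all_slabs(self):
        # octagon-cornered ring: every pixel has exactly 2 neighbors
        cm = classify_pixels(RING)
        assert (cm == SLAB).sum() == 12
        assert (cm == EXTREMITY).sum() == 0
        assert (cm == NODE).sum() == 0

    def test_isolated_pixel_is_extremity(self):
        cm = classify_pixels(raster("..#.."))
        assert (cm == EXTREMITY).sum() == 1


class TestClusterJunctions:
    def test_no_nodes(self):
        assert cluster_junctions(classify_pixels(LINE5)) == []

    def test_diagonal_pair_is_one_junction(self):
        # two crossing paths sharing a diagonally-adjacent node pair
        sk = raster(
            """
#...#
.#.#.
.##..
#..#.
....#
"""
        )
        cm = classify_pixels(sk)
        nodes = np.argwhere(cm == NODE)
        junctions = cluster_junctions(cm)
        if len(nodes) >= 2:
            # all node pixels here are 8-connected: a single junction
            assert len(junctions) == 1

    def test_h_shape_two_junctions(self):
        cm = classify_pixels(H_SHAPE)
        junctions = cluster_junctions(cm)
        assert len(junctions) == 2

    def test_centroid_is_mean_coordinate(self):
        cm = classify_pixels(PLUS_SYMMETRIC)
        (junction,) = cluster_junctions(cm)
        pix = np.array(sorted(junction.pixels))
        assert junction.centroid == pytest.approx(tuple(pix.mean(axis=0)))


class TestTraceEdges:
    def test_five_pixel_line_length(self):
        g = build_skeleton_graph(LINE5)
        assert len(g.edges) == 1
        assert g.edges[0].length == pytest.approx(4.0)

    def test_diagonal_line_length(self):
        g = build_skeleton_graph(DIAG3)
        assert len(g.edges) == 1
        assert g.edges[0].length == pytest.approx(2 * SQRT2)

    def test_diagonal_step_configurable(self):
        g = build_skeleton_graph(DIAG3, diagonal_step=1.0)
        assert g.edges[0].length == pytest.approx(2.0)

    def test_theta_two_junctions_three_edges(self):
        g = build_skeleton_graph(THETA)
        assert len(g.junctions) == 2
        junction_edges = [
            e for e in g.edges if e.end_a[0] == "junction" and e.end_b[0] == "junction"
        ]
        assert len(junction_edges) == 3
        assert len(g.edges) == 3

    def test_pure_ring_single_closed_loop(self):
        g = build_skeleton_graph(RING)
        assert len(g.edges) == 1
        assert g.edges[0].end_a[0] == "loop"
        # 12-pixel octagon-cornered ring: 8 orthogonal + 4 diagonal steps
        assert g.edges[0].length == pytest.approx(8 + 4 * SQRT2)

    def test_plus_edges_attach_to_cluster(self):
        g = build_skeleton_graph(PLUS_SYMMETRIC)
        assert len(g.edges) == 4
        for e in g.edges:
            kinds = {e.end_a[0], e.end_b[0]}
            assert kinds == {"extremity", "junction"}


class TestGraphInvariants:
    @pytest.mark.parametrize("seed", range(12))
    def test_pixel_conservation(self, seed):
        spec = VascularTreeSpec(seed=seed, image_size=128, clearance_px=8)
        skeleton, _ = generate_topology(spec)
        g = build_skeleton_graph(skeleton)
        total = int(skeleton.sum())
        junction_px = sum(j.size for j in g.junctions)
        extremity_px = g.n_extremities
        interior_px = sum(len(e.interior) for e in g.edges)
        assert interior_px + junction_px + extremity_px == total

    @pytest.mark.parametrize("seed", range(12))
    def test_handshake(self, seed):
        spec = VascularTreeSpec(seed=seed, image_size=128, clearance_px=8)
        skeleton, _ = generate_topology(spec)
        g = build_skeleton_graph(skeleton)
        incident = {j.id: 0 for j in g.junctions}
        for e in g.edges:
            for end in (e.end_a, e.end_b):
                if end[0] == "junction":
                    incident[end[1]] += 1
        for j in g.junctions:
            slab_contacts = 0
            seen = set()
            for p in sorted(j.pixels):
                for q in _neighbors(p, g.class_map):
                    if g.class_map[q] == SLAB or g.class_map[q] == EXTREMITY:
                        if q not in seen:
                            seen.add(q)
            # each edge endpoint at this junction consumes one adjacent
            # slab/extremity entry pixel
            assert incident[j.id] <= len(seen) or incident[j.id] == 0

    @pytest.mark.parametrize("seed", range(12))
    def test_cycle_rank_matches_flood_fill(self, seed):
        from conftest import flood_fill_faces

        spec = VascularTreeSpec(seed=seed, image_size=128, clearance_px=8)
        skeleton, _ = generate_topology(spec)
        g = build_skeleton_graph(skeleton)
        assert cycle_rank(g) == len(flood_fill_faces(skeleton))

    def test_trace_determinism(self):
        spec = VascularTreeSpec(seed=5)
        skeleton, _ = generate_topology(spec)
        g1 = build_skeleton_graph(skeleton)
        g2 = build_skeleton_graph(skeleton)
        assert [e.pixels for e in g1.edges] == [e.pixels for e in g2.edges]


def _neighbors(p, cm):
    h, w = cm.shape
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if (dr, dc) == (0, 0):
                continue
            q = (p[0] + dr, p[1] + dc)
            if 0 <= q[0] < h and 0 <= q[1] < w and cm[q]:
                out.append(q)
    return out


class TestPruneSpurs:
    def test_removes_short_twig(self):
        sk = raster(
            """
.........
#########
....#....
....#....
"""
        )
        # 2-step twig off a long line
        pruned = prune_spurs(sk, min_length=3.0)
        g = build_skeleton_graph(pruned)
        assert len(g.junctions) == 0
        assert g.n_extremities == 2

    def test_keeps_long_branches(self):
        sk = raster(
            """
.............
#############
......#......
......#......
......#......
......#......
......#......
"""
        )
        # all three arms exceed the threshold: nothing is pruned
        pruned = prune_spurs(sk, min_length=3.0)
        g = build_skeleton_graph(pruned)
        assert len(g.junctions) == 1
        assert g.n_extremities == 3
        assert int(pruned.sum()) == int(sk.sum())

    def test_noop_on_clean_skeleton(self):
        pruned = prune_spurs(THETA, min_length=3.0)
        assert np.array_equal(pruned, THETA)


def test_json_dump_roundtrips():
    import json

    g = build_skeleton_graph(THETA)
    payload = json.loads(g.to_json())
    assert len(payload["junctions"]) == 2
    assert len(payload["edges"]) == 3
    assert payload["n_components"] == 1
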