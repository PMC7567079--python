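"""Element taxonomy, master structure, meshes and the feature vector."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retvasc.features import (
    FEATURE_NAMES,
    classify_elements,
    compute_features,
    features_from_skeleton,
    find_master_structure,
    find_meshes,
)
from retvasc.graph import build_skeleton_graph
from retvasc.synthetic import VascularTreeSpec, generate_topology

from conftest import (
    PLUS_SYMMETRIC,
    RING,
    THETA,
    brute_force_counts,
    flood_fill_faces,
    raster,
    tailed_theta,
)


def analyze(skeleton, mesh_scope="master"):
    g = build_skeleton_graph(skeleton)
    cl = classify_elements(g)
    ms = find_master_structure(g, cl)
    meshes = find_meshes(g, ms, scope=mesh_scope)
    return g, cl, ms, meshes, compute_features(g, cl, ms, meshes)


class TestClassifyElements:
    def test_lone_line_is_isolated(self):
        sk = np.zeros((12, 14), dtype=bool)
        sk[5, 2:12] = True
        _, cl, _, _, f = analyze(sk)
        assert f["isolated_segments"] == 1
        assert f["branches"] == 0 and f["segments"] == 0

    def test_plus_is_four_branches(self):
        _, cl, _, _, f = analyze(PLUS_SYMMETRIC)
        assert f["branches"] == 4
        assert f["segments"] == 0
        assert f["isolated_segments"] == 0

    def test_theta_three_segments(self):
        _, cl, _, _, f = analyze(THETA)
        assert f["segments"] == 3
        assert f["branches"] == 0
        assert f["isolated_segments"] == 0

    def test_tailed_theta_adds_one_branch(self):
        _, cl, _, _, f = analyze(tailed_theta())
        assert f["segments"] == 3
        assert f["branches"] == 1

    def test_ring_is_isolated(self):
        _, cl, _, _, f = analyze(RING)
        assert f["isolated_segments"] == 1

    def test_two_pixel_stub_is_isolated(self):
        sk = np.zeros((6, 6), dtype=bool)
        sk[2, 2] = sk[2, 3] = True
        _, _, _, _, f = analyze(sk)
        assert f["isolated_segments"] == 1
        assert f["extremities"] == 2


class TestMasterStructure:
    def test_pure_tree_has_no_master(self):
        sk = raster(
            """
.............
#############
......#......
......#......
..#...#......
"""
        )
        _, _, ms, meshes, f = analyze(sk)
        assert f["master_segments"] == 0
        assert f["master_junctions"] == 0
        assert f["meshes"] == 0

    def test_theta_all_master(self):
        _, _, ms, _, f = analyze(THETA)
        assert f["master_segments"] == 3
        assert f["master_junctions"] == 2

    def test_pendant_pruned_master_unchanged(self):
        _, _, _, _, bare = analyze(THETA)
        _, _, _, _, tailed = analyze(tailed_theta())
        for key in ("master_segments", "master_junctions", "meshes", "mesh_area"):
            assert tailed[key] == bare[key]


class TestMeshes:
    def test_junction_free_ring_yields_no_master_mesh(self):
        # ring exception: an isolated ring has no master segments, so the
        # default scope reports 0 meshes even though it encloses area
        _, _, _, meshes, f = analyze(RING, mesh_scope="master")
        assert f["meshes"] == 0

    def test_ring_counts_under_all_scope(self):
        _, _, _, meshes, f = analyze(RING, mesh_scope="all")
        assert f["meshes"] == 1
        assert f["mesh_area"] == flood_fill_faces(RING)[0]

    def test_theta_two_meshes_flood_fill_oracle(self):
        _, _, _, meshes, f = analyze(THETA)
        oracle = flood_fill_faces(THETA)
        assert f["meshes"] == len(oracle) == 2
        assert f["mesh_area"] == sum(oracle)

    def test_mesh_regions_disjoint_and_positive(self):
        _, _, _, meshes, _ = analyze(THETA)
        assert all(m.area > 0 for m in meshes)

    def test_bounding_junctions_of_theta(self):
        g, _, _, meshes, _ = analyze(THETA)
        for m in meshes:
            assert len(m.bounding_junctions) == 2


class TestComputeFeatures:
    def test_empty_graph_all_zero(self):
        f = features_from_skeleton(np.zeros((10, 10), dtype=bool))
        assert all(v == 0 for v in f.values())
        assert set(f) == set(FEATURE_NAMES)

    def test_plus_hand_computation(self):
        f = features_from_skeleton(PLUS_SYMMETRIC)
        assert f["branches"] == 4
        assert f["segments"] == 0
        assert f["pieces"] == 4
        assert f["branching_interval"] == 0  # no segments
        assert f["junctions"] == 1
        assert f["nodes"] == 5  # cluster of 5 node pixels
        assert f["extremities"] == 4

    def test_tailed_theta_ratios(self):
        f = features_from_skeleton(tailed_theta())
        assert f["mesh_index"] == pytest.approx(
            f["master_segment_length"] / 3
        )
        assert f["branching_interval"] == pytest.approx(f["segment_length"] / 1)

    @pytest.mark.parametrize("seed", range(15))
    def test_identity_invariants(self, seed):
        spec = VascularTreeSpec(seed=seed, image_size=128, clearance_px=8)
        skeleton, _ = generate_topology(spec)
        f = features_from_skeleton(skeleton)
        assert f["pieces"] == f["segments"] + f["isolated_segments"] + f["branches"]
        assert f["total_length"] == pytest.approx(
            f["branch_length"] + f["segment_length"] + f["isolated_length"]
        )
        assert f["branching_length"] == pytest.approx(
            f["branch_length"] + f["segment_length"]
        )
        if f["meshes"]:
            assert f["mean_mesh_size"] == pytest.approx(f["mesh_area"] / f["meshes"])
        else:
            assert f["mean_mesh_size"] == 0
        if f["master_segments"]:
            assert f["mesh_index"] == pytest.approx(
                f["master_segment_length"] / f["master_segments"]
            )
        assert f["master_segments"] <= f["segments"]
        assert f["master_junctions"] <= f["junctions"]
        assert all(v >= 0 for v in f.values())

    @pytest.mark.parametrize("seed", range(10))
    def test_mesh_cycle_rank_consistency(self, seed):
        from retvasc.graph import cycle_rank

        spec = VascularTreeSpec(seed=seed + 100, image_size=128, clearance_px=8)
        skeleton, _ = generate_topology(spec)
        g, cl, ms, meshes, f = analyze(skeleton, mesh_scope="all")
        assert f["meshes"] == cycle_rank(g)

    def test_branch_deletion_preserves_meshes(self):
        sk = tailed_theta()
        f0 = features_from_skeleton(sk)
        # delete the pendant tail (a branch edge)
        sk2 = sk.copy()
        sk2[6:, :] = False
        f1 = features_from_skeleton(sk2)
        assert f1["meshes"] == f0["meshes"]
        assert f1["master_segments"] == f0["master_segments"]
        assert f1["master_junctions"] == f0["master_junctions"]


class TestBruteForceOracle:
    COUNT_KEYS = [
        "extremities",
        "nodes",
        "junctions",
        "branches",
        "segments",
        "isolated_segments",
        "master_segments",
        "master_junctions",
        "meshes",
        "mesh_area",
    ]

    def test_fixture_library_matches_oracle(self, fixture_library):
        for name, sk in fixture_library.items():
            f = features_from_skeleton(sk)
            oracle = brute_force_counts(sk)
            for key in self.COUNT_KEYS:
                assert f[key] == oracle[key], f"{name}:{key}"

    @pytest.mark.parametrize("seed", range(8))
    def test_synthetic_matches_oracle(self, seed):
        spec = VascularTreeSpec(seed=seed, image_size=96, clearance_px=8, n_primary=3)
        skeleton, _ = generate_topology(spec)
        f = features_from_skeleton(skeleton)
        oracle = brute_force_counts(skeleton)
        for key in self.COUNT_KEYS:
            assert f[key] == oracle[key], key


@given(st.integers(0, 10_000))
@settings(max_examples=25, deadline=None)
def test_identities_hold_on_arbitrary_seeds(seed):
    spec = VascularTreeSpec(seed=seed, image_size=96, clearance_px=8, n_primary=3)
    skeleton, _ = generate_topology(spec)
    f = features_from_skeleton(skeleton)
    assert f["pieces"] == f["segments"] + f["isolated_segments"] + f["branches"]
    assert f["total_length"] == pytest.approx(
        f["branch_length"] + f["segment_length"] + f["isolated_length"]
    )
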