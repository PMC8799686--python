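"""Branch/joint segmentation of thinned skeletons."""

import numpy as np
import pytest

import voxelskel as vs
from voxelskel.skeleton_graph import (
    classify_voxels,
    export_graph,
    import_graph,
    merge_joint_clusters,
    segment_branches,
)
from voxelskel.thinning import thin

from oracles import betti_oracle


def skeleton_of(cells):
    g = vs.VoxelGrid.from_occupancy(cells, pad=2)
    return thin(g)


@pytest.fixture(scope="module")
def chain_skeleton():
    return skeleton_of({(0, 0, k) for k in range(9)})


@pytest.fixture(scope="module")
def loop_skeleton(torus_skeleton):
    return torus_skeleton


class TestClassify:
    def test_straight_chain_roles(self, chain_skeleton):
        roles = classify_voxels(chain_skeleton)
        counts = {r: list(roles.values()).count(r) for r in set(roles.values())}
        assert counts == {"curve_end": 2, "regular": 7}

    def test_y_junction_has_joint(self, y_skeleton):
        roles = classify_voxels(y_skeleton)
        assert any(r == "joint" for r in roles.values())

    def test_closed_loop_all_regular(self, torus_skeleton):
        roles = classify_voxels(torus_skeleton)
        assert set(roles.values()) == {"regular"}


class TestMergeJoints:
    def test_single_joint_voxel_is_its_own_true_joint(self, y_skeleton):
        roles = classify_voxels(y_skeleton)
        joints = merge_joint_clusters(y_skeleton, roles)
        for j in joints:
            assert j.true_joint not in j.associated

    def test_two_voxel_cluster_forced_split(self):
        # synthetic roles: feed a hand-built skeleton through the merger
        cells = {(0, 0, 0), (0, 0, 1)}
        sk = skeleton_of(cells | {(0, 1, 2), (0, -1, 2), (0, 0, -1)})
        roles = {v.index: "joint" for v in sk.voxels if v.index[2] in (2, 3)}
        for v in sk.voxels:
            roles.setdefault(v.index, "regular")
        joints = merge_joint_clusters(sk, roles)
        clusters = [j for j in joints if len(j.cluster) >= 2]
        for j in clusters:
            assert len(j.associated) == len(j.cluster) - 1

    def test_collinear_cluster_picks_middle(self):
        cells = {(0, 0, k) for k in range(7)}
        sk = skeleton_of(cells)
        roles = {v.index: "regular" for v in sk.voxels}
        trio = [(2, 2, 4), (2, 2, 5), (2, 2, 6)]
        for t in trio:
            roles[t] = "joint"
        joints = merge_joint_clusters(sk, roles)
        cluster = [j for j in joints if len(j.cluster) == 3][0]
        assert cluster.true_joint == (2, 2, 5)


class TestSegmentation:
    def test_y_skeleton_three_branches_one_joint(self, y_skeleton):
        graph = segment_branches(y_skeleton)
        assert len(graph.joints) >= 1
        assert len(graph.curve_ends) == 3
        assert len(graph.branches) == 3

    def test_loop_single_branch_no_joints(self, torus_skeleton):
        graph = segment_branches(torus_skeleton)
        assert len(graph.joints) == 0
        assert len(graph.curve_ends) == 0
        assert len(graph.branches) == 1
        b = graph.branches[0]
        assert b.is_loop and b.end_a == b.end_b

    def test_chain_metric_length(self, chain_skeleton):
        graph = segment_branches(chain_skeleton)
        assert len(graph.branches) == 1
        n = graph.branches[0].voxel_count
        assert graph.branches[0].metric_length == pytest.approx(
            (n - 1) * chain_skeleton.voxel_size
        )

    def test_every_voxel_owned_exactly_once(self, y_skeleton):
        graph = segment_branches(y_skeleton)
        cluster_cells = {c for j in graph.joints for c in j.cluster}
        interior = set()
        for b in graph.branches:
            for v in b.voxels:
                if v not in cluster_cells and v not in graph.curve_ends:
                    assert v not in interior, f"{v} owned twice"
                    interior.add(v)
        total = len(cluster_cells) + len(interior) + len(graph.curve_ends)
        assert total == len(y_skeleton)

    def test_cycle_rank_matches_b1(self, torus_skeleton):
        graph = segment_branches(torus_skeleton)
        b1 = betti_oracle(torus_skeleton.as_grid().data)[1]
        assert graph.cycle_rank == b1 == 1


class TestExport:
    def test_json_roundtrip(self, tmp_path, y_skeleton):
        graph = segment_branches(y_skeleton)
        export_graph(graph, tmp_path / "g.json")
        back = import_graph(tmp_path / "g.json")
        assert len(back.joints) == len(graph.joints)
        assert len(back.branches) == len(graph.branches)
        assert back.curve_ends == graph.curve_ends
        assert set(back.payload) == set(graph.payload)

    def test_graphml_counts(self, tmp_path, y_skeleton):
        import networkx as nx

        graph = segment_branches(y_skeleton)
        export_graph(graph, tmp_path / "g.graphml")
        g = nx.read_graphml(tmp_path / "g.graphml")
        assert g.number_of_nodes() == len(graph.joints) + len(graph.curve_ends)
        assert g.number_of_edges() == len(graph.branches)

    def test_obj_vertex_count(self, tmp_path, y_skeleton):
        graph = segment_branches(y_skeleton)
        export_graph(graph, tmp_path / "g.obj")
        lines = (tmp_path / "g.obj").read_text().splitlines()
        assert sum(1 for l in lines if l.startswith("v ")) == len(y_skeleton)

    def test_unknown_format_raises(self, tmp_path, y_skeleton):
        from voxelskel.errors import InvalidParameterError

        graph = segment_branches(y_skeleton)
        with pytest.raises(InvalidParameterError):
            export_graph(graph, tmp_path / "g.xyz", format="stl")
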