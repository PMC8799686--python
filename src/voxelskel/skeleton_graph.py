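"""Skeleton segmentation: joints, branches and curve ends (step 8).

A skeleton voxel is a curve end (one 26-adjacent skeleton voxel), regular
(two) or a joint voxel (three or more).  Clusters of 26-connected joint
voxels are merged: the member closest to the cluster centroid becomes the
true joint, the rest are associated joint voxels.  Maximal chains of
regular voxels between nodes become branches whose polyline geometry is the
sequence of voxel centers.  Pure loops (cycles with no joint) become
branches with identical endpoints.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .errors import InvalidParameterError
from .thinning import Skeleton, SkeletonVoxel
from .voxel_grid import OFFSETS_26

__all__ = [
    "SkeletonGraph",
    "Joint",
    "Branch",
    "classify_voxels",
    "merge_joint_clusters",
    "segment_branches",
    "export_graph",
    "import_graph",
]

Index = tuple[int, int, int]


@dataclass
class Joint:
    """A true joint and its associated joint voxels."""

    true_joint: Index
    associated: list[Index]
    world: np.ndarray

    @property
    def cluster(self) -> list[Index]:
        return [self.true_joint, *self.associated]


@dataclass
class Branch:
    """Ordered chain of skeleton voxels linking two nodes."""

    voxels: list[Index]          # includes the node endpoints
    end_a: Index
    end_b: Index
    polyline: np.ndarray         # world coordinates of voxel centers
    metric_length: float
    is_loop: bool = False

    @property
    def voxel_count(self) -> int:
        return len(self.voxels)


@dataclass
class SkeletonGraph:
    """Joints + curve ends as nodes, ordered branch chains as edges."""

    joints: list[Joint]
    curve_ends: list[Index]
    branches: list[Branch]
    payload: dict[Index, SkeletonVoxel] = field(default_factory=dict)
    voxel_size: float = 1.0

    @property
    def cycle_rank(self) -> int:
        g = self.to_networkx()
        return len(g.edges) - len(g.nodes) + nx.number_connected_components(g)

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for j in self.joints:
            g.add_node(j.true_joint, kind="joint",
                       associated=len(j.associated))
        for e in self.curve_ends:
            g.add_node(e, kind="curve_end")
        for i, b in enumerate(self.branches):
            g.add_edge(b.end_a, b.end_b, key=i,
                       voxel_count=b.voxel_count,
                       metric_length=b.metric_length,
                       is_loop=b.is_loop)
        return g


def classify_voxels(skeleton: Skeleton) -> dict[Index, str]:
    """Label each skeleton voxel curve-end / regular / joint by 26-degree."""
    occupied = set(v.index for v in skeleton.voxels)
    roles: dict[Index, str] = {}
    for idx in occupied:
        deg = sum(
            (idx[0] + o[0], idx[1] + o[1], idx[2] + o[2]) in occupied
            for o in OFFSETS_26
        )
        if deg <= 1:
            if deg == 0:
                warnings.warn(f"isolated skeleton voxel {idx}", stacklevel=2)
            roles[idx] = "curve_end"
        elif deg == 2:
            roles[idx] = "regular"
        else:
            roles[idx] = "joint"
    return roles


def merge_joint_clusters(skeleton: Skeleton, roles: dict[Index, str]) -> list[Joint]:
    """Merge 26-connected joint-voxel groups; centroid-nearest member is true joint."""
    joint_cells = sorted(i for i, r in roles.items() if r == "joint")
    joint_set = set(joint_cells)
    clusters: list[list[Index]] = []
    seen: set[Index] = set()
    for start in joint_cells:
        if start in seen:
            continue
        comp = [start]
        seen.add(start)
        stack = [start]
        while stack:
            c = stack.pop()
            for o in OFFSETS_26:
                n = (c[0] + o[0], c[1] + o[1], c[2] + o[2])
                if n in joint_set and n not in seen:
                    seen.add(n)
                    comp.append(n)
                    stack.append(n)
        clusters.append(sorted(comp))
    payload = skeleton.by_index()
    joints = []
    for comp in clusters:
        centroid = np.mean([np.array(c, dtype=float) for c in comp], axis=0)
        dists = [float(np.linalg.norm(np.array(c) - centroid)) for c in comp]
        best = min(dists)
        winners = [c for c, d in zip(comp, dists) if np.isclose(d, best)]
        true = min(winners)  # deterministic tie-break: lowest index order
        if len(winners) > 1:
            warnings.warn(f"joint centroid tie in cluster {comp}; chose {true}",
                          stacklevel=2)
        joints.append(Joint(true, [c for c in comp if c != true],
                            payload[true].world))
    return joints


def segment_branches(skeleton: Skeleton, joints: list[Joint] | None = None) -> SkeletonGraph:
    """Walk regular voxels between nodes to produce the segmented graph."""
    roles = classify_voxels(skeleton)
    if joints is None:
        joints = merge_joint_clusters(skeleton, roles)
    payload = skeleton.by_index()
    occupied = set(payload)
    vs = skeleton.voxel_size

    cluster_of: dict[Index, Index] = {}
    for j in joints:
        for c in j.cluster:
            cluster_of[c] = j.true_joint
    curve_ends = sorted(i for i, r in roles.items() if r == "curve_end")
    node_cells = set(cluster_of) | set(curve_ends)

    def nbrs(c: Index) -> list[Index]:
        return [
            (c[0] + o[0], c[1] + o[1], c[2] + o[2])
            for o in OFFSETS_26
            if (c[0] + o[0], c[1] + o[1], c[2] + o[2]) in occupied
        ]

    def node_id(c: Index) -> Index:
        return cluster_of.get(c, c)

    branches: list[Branch] = []
    used_regular: set[Index] = set()
    visited_pairs: set[tuple[Index, Index]] = set()

    def walk(start_node: Index, first: Index) -> None:
        chain = [start_node, first]
        prev, cur = start_node, first
        while cur not in node_cells:
            used_regular.add(cur)
            nxt = [n for n in nbrs(cur) if n != prev and (n not in chain[:-1])]
            # prefer unvisited regular continuation; a regular voxel has
            # exactly two neighbours so this is deterministic
            nxt = [n for n in nxt if n not in used_regular or n in node_cells]
            if not nxt:
                break
            step = min(nxt)
            chain.append(step)
            prev, cur = cur, step
        _add_branch(chain)

    def _add_branch(chain: list[Index]) -> None:
        a, b = node_id(chain[0]), node_id(chain[-1])
        key = (min(a, b), max(a, b), chain[1] if len(chain) > 1 else a)
        pts = np.array([payload[c].world for c in chain], dtype=float)
        length = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))) if len(pts) > 1 else 0.0
        branches.append(Branch(chain, a, b, pts, length, is_loop=a == b and len(chain) > 2))

    for j in joints:
        for c in j.cluster:
            for n in nbrs(c):
                if n in cluster_of and cluster_of[n] == j.true_joint:
                    continue
                if roles.get(n) == "regular":
                    if n in used_regular:
                        continue
                    walk(c, n)
                elif n in node_cells:
                    pair = tuple(sorted((c, n)))
                    if pair not in visited_pairs:
                        visited_pairs.add(pair)
                        _add_branch([c, n])
    for e in curve_ends:
        for n in nbrs(e):
            if roles.get(n) == "regular" and n not in used_regular:
                walk(e, n)
            elif n in node_cells:
                pair = tuple(sorted((e, n)))
                if pair not in visited_pairs:
                    visited_pairs.add(pair)
                    _add_branch([e, n])
    # pure loops: regular voxels not yet claimed by any walk
    remaining = sorted(
        i for i, r in roles.items() if r == "regular" and i not in used_regular
    )
    remaining_set = set(remaining)
    while remaining_set:
        start = min(remaining_set)
        chain = [start]
        remaining_set.discard(start)
        used_regular.add(start)
        prev, cur = None, start
        while True:
            options = [n for n in nbrs(cur) if n != prev and n in remaining_set]
            if not options:
                break
            step = min(options)
            chain.append(step)
            remaining_set.discard(step)
            used_regular.add(step)
            prev, cur = cur, step
        chain.append(start)  # close the loop
        _add_branch(chain)
    return SkeletonGraph(joints, curve_ends, branches, payload, vs)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_graph(graph: SkeletonGraph, path: str | Path, format: str | None = None) -> None:
    """Write the graph as JSON, GraphML or OBJ polylines (by extension)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "json":
        doc = {
            "voxel_size": graph.voxel_size,
            "joints": [
                {"true_joint": list(j.true_joint),
                 "associated": [list(a) for a in j.associated],
                 "world": [float(v) for v in j.world]}
                for j in graph.joints
            ],
            "curve_ends": [list(e) for e in graph.curve_ends],
            "branches": [
                {"voxels": [list(v) for v in b.voxels],
                 "end_a": list(b.end_a), "end_b": list(b.end_b),
                 "polyline": b.polyline.tolist(),
                 "metric_length": b.metric_length,
                 "is_loop": b.is_loop}
                for b in graph.branches
            ],
            "payload": {
                ",".join(map(str, i)): {
                    "world": [float(v) for v in p.world],
                    "exposure": list(p.exposure),
                    "exposed_faces": p.exposed_faces,
                }
                for i, p in graph.payload.items()
            },
        }
        path.write_text(json.dumps(doc, default=int))
    elif fmt == "graphml":
        g = nx.MultiGraph()
        ng = graph.to_networkx()
        for n, d in ng.nodes(data=True):
            g.add_node(",".join(map(str, n)), **d)
        for a, b, k, d in ng.edges(keys=True, data=True):
            g.add_edge(",".join(map(str, a)), ",".join(map(str, b)), key=k, **d)
        nx.write_graphml(g, path)
    elif fmt == "obj":
        with open(path, "w") as fh:
            vid = {}
            for i, (idx, p) in enumerate(sorted(graph.payload.items()), start=1):
                vid[idx] = i
                fh.write(f"v {p.world[0]:.6f} {p.world[1]:.6f} {p.world[2]:.6f}\n")
            for b in graph.branches:
                ids = " ".join(str(vid[v]) for v in b.voxels if v in vid)
                fh.write(f"l {ids}\n")
    else:
        raise InvalidParameterError(f"unknown graph export format: {fmt}")


def import_graph(path: str | Path) -> SkeletonGraph:
    """Read back a JSON export (lossless round-trip)."""
    doc = json.loads(Path(path).read_text())
    payload = {}
    for key, p in doc["payload"].items():
        idx = tuple(int(v) for v in key.split(","))
        payload[idx] = SkeletonVoxel(
            index=idx,
            world=np.array(p["world"]),
            exposure=tuple(p["exposure"]),
            exposed_faces=p["exposed_faces"],
            face_exposure={},
        )
    joints = [
        Joint(tuple(j["true_joint"]), [tuple(a) for a in j["associated"]],
              np.array(j["world"]))
        for j in doc["joints"]
    ]
    branches = [
        Branch([tuple(v) for v in b["voxels"]], tuple(b["end_a"]), tuple(b["end_b"]),
               np.array(b["polyline"]), b["metric_length"], b["is_loop"])
        for b in doc["branches"]
    ]
    return SkeletonGraph(joints, [tuple(e) for e in doc["curve_ends"]],
                         branches, payload, doc["voxel_size"])
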