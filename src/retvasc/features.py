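"""Edge taxonomy, master-structure resolution, mesh detection and the
per-image feature vector.

Element classes
---------------
branch    : exactly one endpoint is an extremity, the other a junction
segment   : both endpoints are junctions (self-loops included)
isolated  : the edge lies in a connected component containing no junction
            (lone lines, 2-pixel stubs and junction-free rings), plus the
            degenerate extremity-extremity case inside a junction-bearing
            component

The master structure is obtained by fixpoint pruning of the segment-only
subgraph: any segment with an endpoint junction of degree 1 is deleted,
repeatedly, until stable. Surviving segments are master segments; junctions
incident to >=3 of them are master junctions. Meshes are the bounded
background faces of the rasterized master subgraph (4-connected flood fill
from the border); a junction-free ring therefore bounds no mesh under the
default scope, because it contributes no master segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .graph import SkeletonGraph

FEATURE_NAMES = [
    "extremities",
    "nodes",
    "junctions",
    "branches",
    "branch_length",
    "segments",
    "segment_length",
    "isolated_segments",
    "isolated_length",
    "master_segments",
    "master_segment_length",
    "master_junctions",
    "meshes",
    "mesh_area",
    "mean_mesh_size",
    "mesh_index",
    "branching_interval",
    "pieces",
    "total_length",
    "branching_length",
]

BRANCH = "branch"
SEGMENT = "segment"
ISOLATED = "isolated"


@dataclass
class ElementClassification:
    """Per-edge class plus the edge-id partitions used downstream."""

    edge_class: dict  # edge id -> BRANCH | SEGMENT | ISOLATED
    branches: list = field(default_factory=list)
    segments: list = field(default_factory=list)
    isolated: list = field(default_factory=list)


@dataclass(frozen=True)
class Mesh:
    id: int
    area: int
    bounding_junctions: frozenset


@dataclass
class MasterStructure:
    master_segment_ids: set
    master_junction_ids: set


def classify_elements(graph: SkeletonGraph) -> ElementClassification:
    """Assign every edge to branch / segment / isolated."""
    junction_comps = set(graph.junction_components().values())
    out = ElementClassification(edge_class={})
    for e in graph.edges:
        kinds = {e.end_a[0], e.end_b[0]}
        if kinds == {"loop"}:
            cls = ISOLATED
        elif kinds == {"junction"}:
            cls = SEGMENT
        elif kinds == {"junction", "extremity"}:
            cls = BRANCH if e.component in junction_comps else ISOLATED
        else:  # extremity-extremity: isolated-like even beside a junction
            cls = ISOLATED
        out.edge_class[e.id] = cls
        getattr(out, {"branch": "branches", "segment": "segments", "isolated": "isolated"}[cls]).append(e.id)
    return out


def find_master_structure(
    graph: SkeletonGraph, classification: ElementClassification
) -> MasterStructure:
    """Fixpoint pruning of the segment-only junction multigraph."""
    edges = {e.id: e for e in graph.edges}
    alive = set(classification.segments)
    incident: dict = {j.id: set() for j in graph.junctions}
    for eid in alive:
        e = edges[eid]
        incident[e.end_a[1]].add(eid)
        incident[e.end_b[1]].add(eid)

    def degree(jid):
        # self-loops count twice toward pruning degree
        d = 0
        for eid in incident[jid]:
            e = edges[eid]
            d += 2 if e.end_a[1] == e.end_b[1] else 1
        return d

    changed = True
    while changed:
        changed = False
        for jid in list(incident):
            if degree(jid) == 1:
                (eid,) = [e for e in incident[jid]]
                e = edges[eid]
                incident[e.end_a[1]].discard(eid)
                incident[e.end_b[1]].discard(eid)
                alive.discard(eid)
                changed = True

    master_junctions = {
        jid for jid, eids in incident.items() if len(eids) >= 3
    }
    return MasterStructure(master_segment_ids=alive, master_junction_ids=master_junctions)


def _bounded_regions(raster: np.ndarray) -> list:
    """Areas of 4-connected background regions not touching the border."""
    background = ~raster
    labels, n = ndimage.label(background, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool))
    if n == 0:
        return []
    border = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return [
        (lab, int(areas[lab - 1]))
        for lab in range(1, n + 1)
        if lab not in border
    ]


def find_meshes(
    graph: SkeletonGraph,
    master: MasterStructure,
    scope: str = "master",
) -> list:
    """Flood-fill the faces bounded by the master subgraph (or, with
    ``scope='all'``, by the full skeleton)."""
    raster = np.zeros(graph.shape, dtype=bool)
    if scope == "all":
        raster = graph.class_map > 0
    elif scope == "master":
        edges = {e.id: e for e in graph.edges}
        touched_junctions = set()
        for eid in master.master_segment_ids:
            e = edges[eid]
            for r, c in e.pixels:
                raster[r, c] = True
            touched_junctions.add(e.end_a[1])
            touched_junctions.add(e.end_b[1])
        for j in graph.junctions:
            if j.id in touched_junctions:
                for r, c in j.pixels:
                    raster[r, c] = True
    else:
        raise ValueError("scope must be 'master' or 'all'")

    meshes = []
    junctions_by_pixel = {}
    for j in graph.junctions:
        for p in j.pixels:
            junctions_by_pixel[p] = j.id
    labels, _ = ndimage.label(~raster, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool))
    for mid, (lab, area) in enumerate(_bounded_regions(raster)):
        region = labels == lab
        ring = ndimage.binary_dilation(region, np.ones((3, 3), dtype=bool)) & raster
        bounding = frozenset(
            junctions_by_pixel[p]
            for p in zip(*np.nonzero(ring))
            if p in junctions_by_pixel
        )
        meshes.append(Mesh(id=mid, area=area, bounding_junctions=bounding))
    return meshes


def compute_features(
    graph: SkeletonGraph,
    classification: ElementClassification,
    master: MasterStructure,
    meshes: list,
) -> dict:
    """Assemble the 20-metric feature vector for one image.

    Ratio features with empty denominators are reported as 0 so tables
    stay total; counts are node *pixels* for ``nodes`` and node *clusters*
    for ``junctions``.
    """
    edges = {e.id: e for e in graph.edges}

    def tot(ids):
        return float(sum(edges[i].length for i in ids))

    nb_branches = len(classification.branches)
    nb_segments = len(classification.segments)
    nb_isolated = len(classification.isolated)
    branch_length = tot(classification.branches)
    segment_length = tot(classification.segments)
    isolated_length = tot(classification.isolated)
    nb_master_segments = len(master.master_segment_ids)
    master_segment_length = tot(master.master_segment_ids)
    nb_meshes = len(meshes)
    mesh_area = float(sum(m.area for m in meshes))

    out = {
        "extremities": float(graph.n_extremities),
        "nodes": float(graph.n_node_pixels),
        "junctions": float(len(graph.junctions)),
        "branches": float(nb_branches),
        "branch_length": branch_length,
        "segments": float(nb_segments),
        "segment_length": segment_length,
        "isolated_segments": float(nb_isolated),
        "isolated_length": isolated_length,
        "master_segments": float(nb_master_segments),
        "master_segment_length": master_segment_length,
        "master_junctions": float(len(master.master_junction_ids)),
        "meshes": float(nb_meshes),
        "mesh_area": mesh_area,
        "mean_mesh_size": mesh_area / nb_meshes if nb_meshes else 0.0,
        "mesh_index": (
            master_segment_length / nb_master_segments if nb_master_segments else 0.0
        ),
        "branching_interval": segment_length / nb_branches if nb_branches else 0.0,
        "pieces": float(nb_segments + nb_isolated + nb_branches),
        "total_length": branch_length + segment_length + isolated_length,
        "branching_length": branch_length + segment_length,
    }
    return out


def features_from_skeleton(
    skeleton: np.ndarray,
    diagonal_step: float = 2.0**0.5,
    mesh_scope: str = "master",
) -> dict:
    """Convenience: full feature vector straight from a skeleton raster."""
    from .graph import build_skeleton_graph

    graph = build_skeleton_graph(skeleton, diagonal_step=diagonal_step)
    classification = classify_elements(graph)
    master = find_master_structure(graph, classification)
    meshes = find_meshes(graph, master, scope=mesh_scope)
    return compute_features(graph, classification, master, meshes)
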