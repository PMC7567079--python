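"""Skeleton raster -> explicit graph of classified pixels, junctions and edges.

Pixel classes follow the neighbor-count rule over the 8-neighborhood
restricted to skeleton pixels: 1 neighbor -> extremity, 2 -> slab,
>=3 -> node (0 -> degenerate lone extremity). Junctions are 8-connected
clusters of node pixels and act as single graph vertices; edges are traced
slab paths between junctions/extremities, with pure slab cycles kept as
closed-loop edges.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

EXTREMITY = 1
SLAB = 2
NODE = 3

_STRUCT8 = np.ones((3, 3), dtype=bool)

# lexicographic (row, col) neighbor order => deterministic traversal
_NEIGHBOR_OFFSETS = [
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
]


@dataclass(frozen=True)
class Junction:
    """An 8-connected cluster of node pixels collapsed to one vertex."""

    id: int
    pixels: frozenset
    centroid: tuple

    @property
    def size(self) -> int:
        return len(self.pixels)


@dataclass
class Edge:
    """A traced path. Endpoints are ('junction', id), ('extremity', (r, c))
    or ('loop', None) for a junction-free cycle."""

    id: int
    end_a: tuple
    end_b: tuple
    pixels: list  # ordered path incl. terminal pixels; for loops, the cycle
    length: float
    component: int = -1

    @property
    def interior(self) -> list:
        """Slab pixels owned exclusively by this edge (terminal extremity
        and junction pixels excluded; loops own their whole cycle)."""
        if self.end_a[0] == "loop":
            return self.pixels
        return self.pixels[1:-1]


@dataclass
class SkeletonGraph:
    shape: tuple
    class_map: np.ndarray  # 0 background, else EXTREMITY/SLAB/NODE
    junctions: list = field(default_factory=list)
    edges: list = field(default_factory=list)
    component_labels: np.ndarray | None = None
    n_components: int = 0

    @property
    def extremity_pixels(self) -> list:
        rr, cc = np.nonzero(self.class_map == EXTREMITY)
        return list(zip(rr.tolist(), cc.tolist()))

    @property
    def n_extremities(self) -> int:
        return int(np.count_nonzero(self.class_map == EXTREMITY))

    @property
    def n_node_pixels(self) -> int:
        return int(np.count_nonzero(self.class_map == NODE))

    def component_of(self, pixel: tuple) -> int:
        return int(self.component_labels[pixel])

    def junction_components(self) -> dict:
        """Map junction id -> skeleton component label."""
        return {
            j.id: self.component_of(next(iter(j.pixels))) for j in self.junctions
        }

    def to_json(self) -> str:
        """Debug/oracle dump of junction centroids and edge endpoints."""
        payload = {
            "junctions": [
                {
                    "id": j.id,
                    "size": j.size,
                    "centroid": list(j.centroid),
                    "pixels": sorted(map(list, j.pixels)),
                }
                for j in self.junctions
            ],
            "edges": [
                {
                    "id": e.id,
                    "end_a": [e.end_a[0], list(e.end_a[1]) if isinstance(e.end_a[1], tuple) else e.end_a[1]],
                    "end_b": [e.end_b[0], list(e.end_b[1]) if isinstance(e.end_b[1], tuple) else e.end_b[1]],
                    "length": e.length,
                    "n_pixels": len(e.pixels),
                }
                for e in self.edges
            ],
            "n_components": self.n_components,
        }
        return json.dumps(payload, indent=2)


def classify_pixels(skeleton: np.ndarray) -> np.ndarray:
    """Per-pixel class map from skeleton-restricted 8-neighbor counts."""
    skeleton = np.asarray(skeleton, dtype=bool)
    counts = ndimage.convolve(
        skeleton.astype(np.uint8),
        np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8),
        mode="constant",
        cval=0,
    )
    class_map = np.zeros(skeleton.shape, dtype=np.uint8)
    class_map[skeleton & (counts <= 1)] = EXTREMITY
    class_map[skeleton & (counts == 2)] = SLAB
    class_map[skeleton & (counts >= 3)] = NODE
    return class_map


def cluster_junctions(class_map: np.ndarray) -> list:
    """8-connected components of node pixels, with mean-coordinate centroids."""
    nodes = class_map == NODE
    labels, n = ndimage.label(nodes, structure=_STRUCT8)
    junctions = []
    if n:
        objects = ndimage.find_objects(labels)
        for jid in range(1, n + 1):
            sl = objects[jid - 1]
            rr, cc = np.nonzero(labels[sl] == jid)
            rr = rr + sl[0].start
            cc = cc + sl[1].start
            pix = frozenset(zip(rr.tolist(), cc.tolist()))
            junctions.append(
                Junction(
                    id=jid - 1,
                    pixels=pix,
                    centroid=(float(rr.mean()), float(cc.mean())),
                )
            )
    return junctions


def _skeleton_neighbors(pixel, class_map):
    h, w = class_map.shape
    r, c = pixel
    out = []
    for dr, dc in _NEIGHBOR_OFFSETS:
        rr, cc = r + dr, c + dc
        if 0 <= rr < h and 0 <= cc < w and class_map[rr, cc]:
            out.append((rr, cc))
    return out


def _path_length(pixels, diagonal_step: float, closed: bool = False) -> float:
    total = 0.0
    pairs = zip(pixels, pixels[1:])
    for (r1, c1), (r2, c2) in pairs:
        total += diagonal_step if (r1 != r2 and c1 != c2) else 1.0
    if closed and len(pixels) > 1:
        (r1, c1), (r2, c2) = pixels[-1], pixels[0]
        total += diagonal_step if (r1 != r2 and c1 != c2) else 1.0
    return total


def trace_edges(
    class_map: np.ndarray,
    junctions: list,
    diagonal_step: float = math.sqrt(2.0),
) -> list:
    """Trace every edge of the skeleton graph deterministically.

    Walks start at extremities, then at slab pixels adjacent to junction
    clusters, consuming each slab pixel exactly once; leftover slab pixels
    form pure cycles and are emitted as closed-loop edges. Edge length is
    the sum of step costs (orthogonal 1, diagonal ``diagonal_step``) along
    the full path including the terminal extremity/node pixels.
    """
    junction_of = {}
    for j in junctions:
        for p in j.pixels:
            junction_of[p] = j.id

    def endpoint(pixel):
        if class_map[pixel] == NODE:
            return ("junction", junction_of[pixel])
        return ("extremity", pixel)

    visited_slab = set()
    consumed_extremity = set()
    edges = []

    def walk(start, first):
        """Follow slab pixels from `start` through `first` to a terminal."""
        path = [start]
        prev, cur = start, first
        while class_map[cur] == SLAB:
            visited_slab.add(cur)
            path.append(cur)
            nbrs = _skeleton_neighbors(cur, class_map)
            nxt = [p for p in nbrs if p != prev]
            if len(nxt) != 1:
                raise RuntimeError(
                    f"slab pixel {cur} has {len(nbrs)} skeleton neighbors; "
                    "thinning invariant violated"
                )
            prev, cur = cur, nxt[0]
        path.append(cur)
        return path

    def emit(path):
        a, b = endpoint(path[0]), endpoint(path[-1])
        for end in (a, b):
            if end[0] == "extremity":
                consumed_extremity.add(end[1])
        edges.append(
            Edge(
                id=len(edges),
                end_a=a,
                end_b=b,
                pixels=path,
                length=_path_length(path, diagonal_step),
            )
        )

    # pass 1: from extremities
    rr, cc = np.nonzero(class_map == EXTREMITY)
    for start in sorted(zip(rr.tolist(), cc.tolist())):
        if start in consumed_extremity:
            continue
        nbrs = _skeleton_neighbors(start, class_map)
        if not nbrs:  # isolated single pixel: vertex only
            consumed_extremity.add(start)
            continue
        (first,) = nbrs
        if class_map[first] == SLAB and first in visited_slab:
            continue
        if class_map[first] == EXTREMITY:  # 2-pixel component
            emit([start, first])
            continue
        if class_map[first] == NODE:
            emit([start, first])
            continue
        emit(walk(start, first))

    # pass 2: from slab pixels hugging junctions
    for j in junctions:
        for node_pix in sorted(j.pixels):
            for nbr in _skeleton_neighbors(node_pix, class_map):
                if class_map[nbr] == SLAB and nbr not in visited_slab:
                    emit(walk(node_pix, nbr))

    # pass 3: leftover slabs are pure cycles
    rr, cc = np.nonzero(class_map == SLAB)
    for start in sorted(zip(rr.tolist(), cc.tolist())):
        if start in visited_slab:
            continue
        visited_slab.add(start)
        cycle = [start]
        nbrs = _skeleton_neighbors(start, class_map)
        prev, cur = start, nbrs[0]
        while cur != start:
            visited_slab.add(cur)
            cycle.append(cur)
            nxt = [p for p in _skeleton_neighbors(cur, class_map) if p != prev]
            prev, cur = cur, nxt[0]
        edges.append(
            Edge(
                id=len(edges),
                end_a=("loop", None),
                end_b=("loop", None),
                pixels=cycle,
                length=_path_length(cycle, diagonal_step, closed=True),
            )
        )
    return edges


def build_skeleton_graph(
    skeleton: np.ndarray, diagonal_step: float = math.sqrt(2.0)
) -> SkeletonGraph:
    """Full graph construction: classify, cluster, trace, label components."""
    skeleton = np.asarray(skeleton, dtype=bool)
    class_map = classify_pixels(skeleton)
    junctions = cluster_junctions(class_map)
    edges = trace_edges(class_map, junctions, diagonal_step=diagonal_step)
    labels, n = ndimage.label(skeleton, structure=_STRUCT8)
    graph = SkeletonGraph(
        shape=skeleton.shape,
        class_map=class_map,
        junctions=junctions,
        edges=edges,
        component_labels=labels,
        n_components=int(n),
    )
    for e in graph.edges:
        e.component = int(labels[e.pixels[0]])
    return graph


def cycle_rank(graph: SkeletonGraph) -> int:
    """Sum over components of E - V + 1, with junctions and extremities as
    vertices (closed loops count one cycle each)."""
    per_comp_v: dict = {}
    per_comp_e: dict = {}
    comp_of_junction = graph.junction_components()
    for jid, comp in comp_of_junction.items():
        per_comp_v[comp] = per_comp_v.get(comp, 0) + 1
    for p in graph.extremity_pixels:
        comp = graph.component_of(p)
        per_comp_v[comp] = per_comp_v.get(comp, 0) + 1
    loops = 0
    for e in graph.edges:
        if e.end_a[0] == "loop":
            loops += 1
            continue
        per_comp_e[e.component] = per_comp_e.get(e.component, 0) + 1
    total = loops
    for comp, v in per_comp_v.items():
        total += per_comp_e.get(comp, 0) - v + 1
    return total


def prune_spurs(
    skeleton: np.ndarray,
    min_length: float,
    diagonal_step: float = math.sqrt(2.0),
    max_passes: int = 8,
) -> np.ndarray:
    """Remove short extremity-junction twigs left behind by thinning.

    A spur is a branch edge (one extremity endpoint, one junction
    endpoint) of length <= ``min_length``; its extremity and interior slab
    pixels are erased and the graph is rebuilt until no spur remains.
    Real vessel tips longer than the threshold are untouched.
    """
    sk = np.asarray(skeleton, dtype=bool).copy()
    for _ in range(max_passes):
        graph = build_skeleton_graph(sk, diagonal_step=diagonal_step)
        doomed = []
        for e in graph.edges:
            ends = {e.end_a[0], e.end_b[0]}
            if ends == {"extremity", "junction"} and e.length <= min_length:
                doomed.append(e)
        if not doomed:
            break
        for e in doomed:
            for p in e.pixels:
                if graph.class_map[p] != NODE:
                    sk[p] = False
        # a pruned twig can leave its anchor node pixel dangling as a bump
        # on a through-path; re-thinning absorbs it without changing
        # topology
        from skimage.morphology import skeletonize as _thin

        sk = _thin(sk)
    return sk
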