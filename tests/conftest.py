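"""Shared fixtures: hand-built skeleton rasters and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest


def raster(art: str) -> np.ndarray:
    """Build a boolean raster from ASCII art ('#' = foreground)."""
    lines = [ln for ln in art.strip("\n").splitlines()]
    width = max(len(ln) for ln in lines)
    out = np.zeros((len(lines), width), dtype=bool)
    for r, ln in enumerate(lines):
        for c, ch in enumerate(ln):
            if ch == "#":
                out[r, c] = True
    return out


# --- canonical hand-built fixtures ------------------------------------------

# 4 arms of 2 px meeting at one center pixel
PLUS_SYMMETRIC = raster(
    """
.......
...#...
...#...
.#####.
...#...
...#...
.......
"""
)

H_SHAPE = raster(
    """
#...#
#...#
#####
#...#
#...#
"""
)

# corners cut diagonally: a plain rectangle would create spurious node
# pixels beside each corner through 8-connected diagonal shortcuts
RING = raster(
    """
.......
..###..
.#...#.
.#...#.
.#...#.
..###..
.......
"""
)

# two loops sharing a vertical chord => theta
THETA = raster(
    """
...........
..##.##....
.#..#..#...
.#..#..#...
.#..#..#...
..##.##....
...........
"""
)

LINE5 = raster("#####")

DIAG3 = raster(
    """
#..
.#.
..#
"""
)


def tailed_theta() -> np.ndarray:
    """Theta with a short pendant tail joining the bottom chord junction."""
    art = """
...........
..##.##....
.#..#..#...
.#..#..#...
.#..#..#...
..##.##....
...#.......
...#.......
...#.......
...........
"""
    return raster(art)


@pytest.fixture
def fixture_library():
    return {
        "plus": PLUS_SYMMETRIC,
        "theta": THETA,
        "ring": RING,
        "h": H_SHAPE,
        "tailed_theta": tailed_theta(),
    }


# --- independent oracles -----------------------------------------------------


def flood_fill_faces(skeleton: np.ndarray) -> list[int]:
    """Bounded 4-connected background regions of a raster, by explicit BFS
    flood fill (no scipy); returns their areas."""
    h, w = skeleton.shape
    seen = np.zeros_like(skeleton, dtype=bool)
    areas = []
    for r0 in range(h):
        for c0 in range(w):
            if skeleton[r0, c0] or seen[r0, c0]:
                continue
            stack = [(r0, c0)]
            seen[r0, c0] = True
            region = []
            touches_border = False
            while stack:
                r, c = stack.pop()
                region.append((r, c))
                if r in (0, h - 1) or c in (0, w - 1):
                    touches_border = True
                for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and not skeleton[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
            if not touches_border:
                areas.append(len(region))
    return sorted(areas)


def count_components_and_holes(mask: np.ndarray) -> tuple[int, int]:
    """(8-connected foreground components, bounded 4-connected holes) by
    explicit flood fill — the conservation oracle for thinning."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = 0
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            comps += 1
            stack = [(r0, c0)]
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
    return comps, len(flood_fill_faces(mask))


def brute_force_counts(skeleton: np.ndarray) -> dict:
    """Exhaustive pixel-neighborhood enumeration of every structural count.

    Written independently of the package's tracer: classifies pixels by
    direct neighbor loops, clusters node pixels by BFS, identifies edges as
    the connected fragments left after deleting node pixels, resolves the
    master subgraph by iterative pruning of a networkx multigraph, and
    counts meshes by flood fill over the rasterized master subgraph.
    """
    import networkx as nx

    h, w = skeleton.shape
    pix = [(r, c) for r in range(h) for c in range(w) if skeleton[r, c]]
    pixset = set(pix)

    def nbrs(p):
        r, c = p
        return [
            (r + dr, c + dc)
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr, dc) != (0, 0) and (r + dr, c + dc) in pixset
        ]

    degree = {p: len(nbrs(p)) for p in pix}
    extremities = [p for p in pix if degree[p] <= 1]
    nodes = [p for p in pix if degree[p] >= 3]

    G = nx.Graph()
    G.add_nodes_from(pix)
    for p in pix:
        for q in nbrs(p):
            G.add_edge(p, q)

    # junction clusters
    nodeset = set(nodes)
    Gn = G.subgraph(nodeset)
    clusters = [frozenset(c) for c in nx.connected_components(Gn)]
    cluster_of = {}
    for i, cl in enumerate(clusters):
        for p in cl:
            cluster_of[p] = i

    # edges = connected fragments of non-node pixels (plus their junction
    # attachments); rings are components with no nodes and no extremities
    nonnode = set(pix) - nodeset
    Gf = G.subgraph(nonnode)
    n_branches = n_segments = n_isolated = 0
    segment_edges = []  # (cluster_a, cluster_b) pairs for the master oracle
    comp_of = {}
    for i, comp in enumerate(nx.connected_components(G)):
        for p in comp:
            comp_of[p] = i
    comp_has_node = {}
    for p in nodeset:
        comp_has_node[comp_of[p]] = True
    comp_sizes = {}
    for p in pix:
        comp_sizes[comp_of[p]] = comp_sizes.get(comp_of[p], 0) + 1

    for frag in nx.connected_components(Gf):
        frag = set(frag)
        comp = comp_of[next(iter(frag))]
        ext_in_frag = sum(1 for p in frag if degree[p] <= 1)
        if not comp_has_node.get(comp, False):
            if comp_sizes[comp] >= 2:
                n_isolated += 1
            continue
        touching = {
            cluster_of[q]
            for p in frag
            for q in nbrs(p)
            if q in nodeset
        }
        if ext_in_frag >= 2:
            n_isolated += 1
        elif ext_in_frag == 1:
            n_branches += 1
        else:
            t = sorted(touching)
            if len(t) == 1:
                segment_edges.append((t[0], t[0], frozenset(frag)))
            else:
                segment_edges.append((t[0], t[1], frozenset(frag)))
            n_segments += 1

    # master structure: iteratively drop segments at degree-1 clusters
    alive = list(range(len(segment_edges)))
    changed = True
    while changed:
        changed = False
        deg = {}
        for idx in alive:
            a, b, _ = segment_edges[idx]
            deg[a] = deg.get(a, 0) + (2 if a == b else 1)
            if a != b:
                deg[b] = deg.get(b, 0) + 1
        for idx in list(alive):
            a, b, _ = segment_edges[idx]
            if a != b and (deg.get(a) == 1 or deg.get(b) == 1):
                alive.remove(idx)
                changed = True
                break
    master_incident = {}
    for idx in alive:
        a, b, _ = segment_edges[idx]
        master_incident.setdefault(a, set()).add(idx)
        master_incident.setdefault(b, set()).add(idx)
    n_master_junctions = sum(1 for s in master_incident.values() if len(s) >= 3)

    master_raster = np.zeros_like(skeleton)
    touched = set()
    for idx in alive:
        a, b, frag = segment_edges[idx]
        touched.update((a, b))
        for p in frag:
            master_raster[p] = True
    for i, cl in enumerate(clusters):
        if i in touched:
            for p in cl:
                master_raster[p] = True
    mesh_areas = flood_fill_faces(master_raster)

    return {
        "extremities": len(extremities),
        "nodes": len(nodes),
        "junctions": len(clusters),
        "branches": n_branches,
        "segments": n_segments,
        "isolated_segments": n_isolated,
        "master_segments": len(alive),
        "master_junctions": n_master_junctions,
        "meshes": len(mesh_areas),
        "mesh_area": sum(mesh_areas),
    }


@pytest.fixture
def small_feature_table():
    """9-row feature table with mild random variation (seeded)."""
    import pandas as pd

    from retvasc.features import FEATURE_NAMES

    rng = np.random.default_rng(77)
    rows = []
    for i in range(9):
        row = {
            "subject_id": f"m{i}",
            "group_label": "wt",
            "timepoint_label": "w0",
        }
        for j, name in enumerate(FEATURE_NAMES):
            row[name] = float(10 + 2 * j + rng.normal(0, 1))
        rows.append(row)
    return pd.DataFrame(rows)
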