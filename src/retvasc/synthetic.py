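"""Synthetic fundus-like images with exact, construction-time ground truth.

Vessels are grown pixel-by-pixel on the integer grid under a strict
collision rule: a new pixel may touch (8-adjacency) only its predecessor —
plus the target tip when an anastomosis arrives. Consequently the raster's
pixel-adjacency graph is exactly the set of drawn steps, so topology
recorded while growing (junctions, endpoints, loops, isolated elements,
centerline length) is exact by construction and never re-measured from the
raster. Truth is fixed at the topology stage; rendering (width dilation,
blur, gradient, noise) never changes it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io import GrayscaleImage

SQRT2 = math.sqrt(2.0)

_OFFSETS = [
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
]


def splitmix64(x: int) -> int:
    """SplitMix64 integer hash; used to derive per-image seeds."""
    x = (x + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return z ^ (z >> 31)


def derive_seed(master_seed: int, *indices: int) -> int:
    h = splitmix64(master_seed & 0xFFFFFFFFFFFFFFFF)
    for i in indices:
        h = splitmix64(h ^ (i & 0xFFFFFFFFFFFFFFFF))
    return h


@dataclass(frozen=True)
class VascularTreeSpec:
    """Parameters of the stochastic radial vessel grower."""

    seed: int = 0
    n_primary: int = 5
    branch_prob: float = 0.08
    branch_angle_deg: float = 40.0
    branch_angle_spread_deg: float = 10.0
    anastomosis_count: int = 2
    fragment_count: int = 4
    fragment_length: int = 8
    vessel_width: tuple = (3, 5)
    image_size: int = 224
    noise_sd: float = 0.02
    background_gradient: float = 0.15
    blur_sigma: float = 0.6
    clearance_px: int = 15
    max_vessel_steps: int = 10_000

    def __post_init__(self) -> None:
        if self.n_primary < 0 or self.anastomosis_count < 0 or self.fragment_count < 0:
            raise ValueError("counts must be >= 0")
        if self.n_primary == 0 and self.anastomosis_count > 0:
            raise ValueError("anastomoses require at least one primary vessel")
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if min(self.vessel_width) < 1:
            raise ValueError("vessel widths must be >= 1 px")
        if not (0 <= self.branch_prob <= 1):
            raise ValueError("branch_prob must be in [0, 1]")


@dataclass
class SyntheticGroundTruth:
    """Exact topology of a generated centerline raster."""

    n_junctions: int
    n_endpoints: int
    n_loops: int
    n_isolated: int
    total_length: float
    n_anastomoses: int
    centerline: np.ndarray

    def to_dict(self) -> dict:
        return {
            "n_junctions": self.n_junctions,
            "n_endpoints": self.n_endpoints,
            "n_loops": self.n_loops,
            "n_isolated": self.n_isolated,
            "total_length": self.total_length,
            "n_anastomoses": self.n_anastomoses,
        }


class _Canvas:
    """Growth ledger: raster + drawn steps + union-find + degrees.

    Besides the strict adjacency rule (a new pixel may touch only its
    predecessor), a clearance rule keeps unrelated structures at least
    ``clearance + 1`` px apart so that width dilation and mask closing in
    the render/analysis chain cannot merge them into false junctions.
    """

    def __init__(self, size: int, clearance: int = 0):
        self.size = size
        self.clearance = clearance
        self.raster = np.zeros((size, size), dtype=bool)
        self.degree: dict = {}
        self.parent: dict = {}
        self.owner: dict = {}  # pixel -> (walker_id, ordinal)
        self.length = 0.0
        self.n_loops = 0

    # union-find over pixels
    def _find(self, p):
        root = p
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[p] != root:
            self.parent[p], p = root, self.parent[p]
        return root

    def add_pixel(self, p, owner: tuple = (-1, 0)) -> None:
        self.raster[p] = True
        self.degree[p] = 0
        self.parent[p] = p
        self.owner[p] = owner

    def add_step(self, a, b) -> None:
        """Record the drawn adjacency a-b (both pixels already placed)."""
        self.degree[a] += 1
        self.degree[b] += 1
        self.length += SQRT2 if (a[0] != b[0] and a[1] != b[1]) else 1.0
        ra, rb = self._find(a), self._find(b)
        if ra == rb:
            self.n_loops += 1
        else:
            self.parent[ra] = rb

    def in_bounds(self, p, margin: int = 2) -> bool:
        return margin <= p[0] < self.size - margin and margin <= p[1] < self.size - margin

    def occupied_neighbors(self, p) -> list:
        out = []
        for dr, dc in _OFFSETS:
            q = (p[0] + dr, p[1] + dc)
            if 0 <= q[0] < self.size and 0 <= q[1] < self.size and self.raster[q]:
                out.append(q)
        return out

    def can_place(self, p, allowed: tuple, ok_far=None) -> bool:
        """Strict adjacency plus, when `ok_far` is given, the clearance
        rule: every occupied pixel within Chebyshev `clearance` of p must
        satisfy ok_far(pixel, owner) or be in `allowed`."""
        if not self.in_bounds(p) or self.raster[p]:
            return False
        if not all(q in allowed for q in self.occupied_neighbors(p)):
            return False
        if ok_far is not None and self.clearance > 1:
            r, c = p
            R = self.clearance
            window = self.raster[
                max(0, r - R): r + R + 1, max(0, c - R): c + R + 1
            ]
            if window.sum() > 0:
                rr, cc = np.nonzero(window)
                for dr, dc in zip(rr.tolist(), cc.tolist()):
                    q = (max(0, r - R) + dr, max(0, c - R) + dc)
                    if q == p or q in allowed:
                        continue
                    if not ok_far(q, self.owner[q]):
                        return False
        return True

    def remove_pixel(self, p) -> None:
        """Rollback helper for failed anastomosis paths (pixel must be
        degree-0 in the ledger or rolled back in reverse order)."""
        self.raster[p] = False
        del self.degree[p]
        del self.parent[p]
        del self.owner[p]


def _offset_for_angle(angle: float) -> tuple:
    idx = int(round(angle / (math.pi / 4))) % 8
    table = [
        (0, 1), (1, 1), (1, 0), (1, -1),
        (0, -1), (-1, -1), (-1, 0), (-1, 1),
    ]
    return table[idx]


@dataclass
class _Walker:
    """A growing vessel tip.

    ``wid`` identifies the walker in the canvas owner ledger; ``trail``
    keeps its recent own pixels (always allowed within the clearance
    window); ``ignore`` holds pixels inherited at spawn (parent trail,
    branch pixel, sibling seed); ``partner`` is the sibling walker id whose
    first few pixels are tolerated while the pair diverges.
    """

    wid: int
    pos: tuple
    angle: float
    steps_since_branch: int = 99
    n_steps: int = 0
    tail_grace: int = 18  # overwritten at spawn: clearance + 6
    trail: list = field(default_factory=list)
    ignore: frozenset = frozenset()
    partner: int = -1
    grace: int = 10

    def ok_far(self, q, owner):
        wid, ordinal = owner
        if wid == self.wid:
            # own path: only the stretch right behind the tip; a vessel
            # curling back toward its older pixels is stopped (endpoint)
            return ordinal >= self.n_steps - self.tail_grace
        if self.n_steps <= self.grace:
            # young walker still near its spawn point: tolerate the pixels
            # inherited there (parent trail, branch pixel, sibling seed)
            if q in self.ignore:
                return True
            if wid == self.partner and ordinal <= self.grace:
                return True
        return False

    def record(self, q, canvas):
        self.n_steps += 1
        self.trail.append(q)
        if len(self.trail) > 2 * canvas.clearance + 8:
            del self.trail[0]


def _try_step(canvas: _Canvas, walker: _Walker, rng) -> bool:
    """Advance one pixel with angular jitter; False when blocked."""
    base = walker.angle + rng.normal(0.0, 0.12)
    for delta in (0.0, 0.35, -0.35, 0.7, -0.7):
        ang = base + delta
        dr, dc = _offset_for_angle(ang)
        q = (walker.pos[0] + dr, walker.pos[1] + dc)
        if canvas.can_place(q, allowed=(walker.pos,), ok_far=walker.ok_far):
            canvas.add_pixel(q, owner=(walker.wid, walker.n_steps))
            canvas.add_step(walker.pos, q)
            walker.pos = q
            walker.angle = ang
            walker.steps_since_branch += 1
            walker.record(q, canvas)
            return True
    return False


def _try_branch(canvas: _Canvas, walker: _Walker, spec: VascularTreeSpec, rng, next_wid):
    """Bifurcate at the walker tip; both children must place cleanly."""
    half = math.radians(
        max(20.0, rng.normal(spec.branch_angle_deg, spec.branch_angle_spread_deg))
    )
    # only the parent's own recent pixels: inheriting the whole ancestor
    # chain would let grandchildren brush along their grandparents
    inherited = frozenset(walker.trail) | {walker.pos}
    placed = []
    children = []
    for i, sign in enumerate((1.0, -1.0)):
        ang = walker.angle + sign * half
        dr, dc = _offset_for_angle(ang)
        q = (walker.pos[0] + dr, walker.pos[1] + dc)
        child = _Walker(
            wid=next_wid + i,
            pos=q,
            angle=ang,
            steps_since_branch=0,
            ignore=inherited,
            partner=next_wid + (1 - i),
            grace=max(10, 2 * canvas.clearance),
            tail_grace=canvas.clearance + 6,
        )
        probe_allowed = (walker.pos,) + tuple(placed)
        if not canvas.can_place(q, allowed=probe_allowed, ok_far=child.ok_far):
            for pp in reversed(placed):
                canvas.remove_pixel(pp)
            return None
        canvas.add_pixel(q, owner=(child.wid, 0))
        child.record(q, canvas)
        placed.append(q)
        children.append(child)
    if max(abs(placed[0][0] - placed[1][0]), abs(placed[0][1] - placed[1][1])) < 2:
        for pp in reversed(placed):
            canvas.remove_pixel(pp)
        return None
    for q in placed:
        canvas.add_step(walker.pos, q)
    return children


def _grow_trees(canvas, roots, spec, rng, max_total_steps):
    """Grow all vessel trees breadth-first from their root walkers."""
    walkers = list(roots)
    next_wid = max(w.wid for w in walkers) + 1 if walkers else 0
    steps = 0
    center = ((canvas.size - 1) / 2.0, (canvas.size - 1) / 2.0)
    r_max = 0.46 * canvas.size
    while walkers and steps < max_total_steps:
        next_walkers = []
        for w in walkers:
            d = math.hypot(w.pos[0] - center[0], w.pos[1] - center[1])
            if d > r_max:
                continue  # reached the field edge: tip becomes an endpoint
            if w.steps_since_branch >= 8 and rng.random() < spec.branch_prob:
                children = _try_branch(canvas, w, spec, rng, next_wid)
                if children is not None:
                    next_wid += 2
                    next_walkers.extend(children)
                    steps += 2
                    continue
            if _try_step(canvas, w, rng):
                next_walkers.append(w)
                steps += 1
            # else: blocked tip -> endpoint, walker dies
        walkers = next_walkers
    return next_wid


def _tip_direction(canvas: _Canvas, tip: tuple):
    """Unit outward direction of the vessel at a tip, from its trail."""
    wid, ordinal = canvas.owner[tip]
    back = None
    best = -1
    for q, (w, o) in canvas.owner.items():
        if w == wid and ordinal - 6 <= o < ordinal and o > best:
            best, back = o, q
    if back is None:
        return None
    d = (tip[0] - back[0], tip[1] - back[1])
    norm = math.hypot(*d)
    return (d[0] / norm, d[1] / norm) if norm else None


def _tip_trail(canvas: _Canvas, tip: tuple) -> dict:
    """Map trail pixels behind a tip to their depth (steps back from the
    tip). The carver relaxes its clearance near the tip and tightens it
    with depth, so a connector can reach the tip but cannot run alongside
    the rest of that vessel."""
    wid, ordinal = canvas.owner[tip]
    reach = 2 * canvas.clearance + 4
    out = {tip: 0}
    for q, (w, o) in canvas.owner.items():
        if w == wid and 0 <= ordinal - o <= reach:
            out[q] = ordinal - o
    return out


def _carve_path(canvas: _Canvas, a: tuple, b: tuple, wid: int) -> bool:
    """Connect tips a and b by a shortest free path (BFS).

    A pixel is usable when it touches no occupied pixel other than the two
    tips and keeps the clearance distance from everything but the tips'
    own short trails. Shortest 8-connected paths contain no non-consecutive
    adjacent pixels, so the drawn steps remain exactly the raster
    adjacencies and the ledger stays exact.
    """
    from collections import deque

    size = canvas.size
    trail_a = _tip_trail(canvas, a)
    trail_b = _tip_trail(canvas, b)
    tolerated = {}
    for q, k in list(trail_a.items()) + list(trail_b.items()):
        tolerated[q] = min(k, tolerated.get(q, k))
    occupied = canvas.raster

    # strict rule: no adjacency to anything but the endpoint tips
    adj_obstacles = occupied.copy()
    adj_obstacles[a] = False
    adj_obstacles[b] = False
    blocked_adj = ndimage.binary_dilation(adj_obstacles, np.ones((3, 3), dtype=bool))

    # clearance rule: stay far from everything except the tip trails,
    # whose required clearance grows with depth behind the tip
    far_obstacles = occupied.copy()
    for q in tolerated:
        far_obstacles[q] = False
    # slightly tighter than growth clearance: the connector is the last
    # structure drawn here, and diagonal Chebyshev distances carry extra
    # Euclidean margin, so corridors stay render-safe
    R = max(8, canvas.clearance - 3)
    if R > 1:
        blocked_far = ndimage.binary_dilation(
            far_obstacles, np.ones((2 * R + 1, 2 * R + 1), dtype=bool)
        )
        for q, k in tolerated.items():
            r = max(0, min(k - 4, R))
            if r:
                blocked_far[
                    max(0, q[0] - r): q[0] + r + 1, max(0, q[1] - r): q[1] + r + 1
                ] = True
    else:
        blocked_far = far_obstacles
    margin = 2
    free = ~occupied & ~blocked_adj & ~blocked_far
    free[:margin, :] = False
    free[-margin:, :] = False
    free[:, :margin] = False
    free[:, -margin:] = False

    def tip_neighbors(tip):
        out = []
        for dr, dc in _OFFSETS:
            q = (tip[0] + dr, tip[1] + dc)
            if 0 <= q[0] < size and 0 <= q[1] < size and free[q]:
                ok = all(
                    nb == tip for nb in canvas.occupied_neighbors(q)
                )
                if ok:
                    out.append(q)
        return out

    goals = set(tip_neighbors(b))
    starts = tip_neighbors(a)
    if not starts or not goals:
        return False
    parent = {q: None for q in starts}
    queue = deque(sorted(starts))
    found = None
    while queue:
        cur = queue.popleft()
        if cur in goals:
            found = cur
            break
        for dr, dc in _OFFSETS:
            q = (cur[0] + dr, cur[1] + dc)
            if q not in parent and 0 <= q[0] < size and 0 <= q[1] < size and free[q]:
                parent[q] = cur
                queue.append(q)
    if found is None:
        return False
    path = [found]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    path.reverse()  # from a-side to b-side
    for i, q in enumerate(path):
        canvas.add_pixel(q, owner=(wid, i))
    canvas.add_step(a, path[0])
    for p1, p2 in zip(path, path[1:]):
        canvas.add_step(p1, p2)
    canvas.add_step(path[-1], b)
    return True


def generate_topology(spec: VascularTreeSpec):
    """Grow the centerline raster; return (raster, SyntheticGroundTruth)."""
    canvas = _Canvas(spec.image_size, clearance=spec.clearance_px)
    rng_grow = np.random.default_rng([spec.seed & 0xFFFFFFFF, 11])
    rng_frag = np.random.default_rng([spec.seed & 0xFFFFFFFF, 13])

    center = ((spec.image_size - 1) / 2.0, (spec.image_size - 1) / 2.0)
    # root ring large enough that neighboring roots respect the clearance
    # (clearance is Chebyshev, so demand sqrt(2) of it in Euclidean chord)
    chord_needed = math.sqrt(2.0) * (spec.clearance_px + 2.0)
    r0 = max(
        6.0,
        0.06 * spec.image_size,
        chord_needed / (2 * math.sin(math.pi / max(spec.n_primary, 2))),
    )

    # primary vessels radiate from a disc-like center
    roots = []
    for k in range(spec.n_primary):
        ang = 2 * math.pi * k / max(spec.n_primary, 1) + rng_grow.normal(0.0, 0.10)
        root = (
            int(round(center[0] + r0 * math.sin(ang))),
            int(round(center[1] + r0 * math.cos(ang))),
        )
        w = _Walker(wid=k, pos=root, angle=ang, tail_grace=canvas.clearance + 6)
        if not canvas.can_place(root, allowed=(), ok_far=w.ok_far):
            continue
        canvas.add_pixel(root, owner=(k, 0))
        w.record(root, canvas)
        roots.append(w)
    next_wid = _grow_trees(canvas, roots, spec, rng_grow, spec.max_vessel_steps)

    # disconnected short fragments
    for _ in range(spec.fragment_count):
        for _attempt in range(60):
            p = (
                int(rng_frag.integers(3, spec.image_size - 3)),
                int(rng_frag.integers(3, spec.image_size - 3)),
            )
            w = _Walker(
                wid=next_wid,
                pos=p,
                angle=rng_frag.uniform(0, 2 * math.pi),
                tail_grace=canvas.clearance + 6,
            )
            if not canvas.can_place(p, allowed=(), ok_far=w.ok_far):
                continue
            canvas.add_pixel(p, owner=(w.wid, 0))
            w.record(p, canvas)
            n = 0
            target = max(2, int(rng_frag.normal(spec.fragment_length, 2)))
            while n < target and _try_step(canvas, w, rng_frag):
                n += 1
            if n == 0:
                canvas.remove_pixel(p)
                continue
            next_wid += 1
            break

    # anastomoses: close loops between nearest same-component tips
    n_anastomoses = 0
    if spec.anastomosis_count > 0:
        tips = [p for p, d in canvas.degree.items() if d == 1]
        # well-separated tips only: close pairs would enclose sliver loops
        # that vessel width and mask closing swallow downstream
        d_min = max(18.0, 0.10 * spec.image_size)
        pairs = []
        for i, a in enumerate(tips):
            for b in tips[i + 1:]:
                if canvas._find(a) != canvas._find(b):
                    continue
                dist = math.hypot(a[0] - b[0], a[1] - b[1])
                if not (d_min <= dist <= 0.5 * spec.image_size):
                    continue
                # the connector must extend both tips, not fold back along
                # them (hairpins merge into blobs once width is rendered)
                u = ((b[0] - a[0]) / dist, (b[1] - a[1]) / dist)
                da, db = _tip_direction(canvas, a), _tip_direction(canvas, b)
                if da is not None and da[0] * u[0] + da[1] * u[1] < -0.7:
                    continue
                if db is not None and db[0] * u[0] + db[1] * u[1] > 0.7:
                    continue
                pairs.append((dist, a, b))
        pairs.sort()
        used = set()
        for dist, a, b in pairs:
            if n_anastomoses >= spec.anastomosis_count:
                break
            if a in used or b in used:
                continue
            if canvas.degree[a] != 1 or canvas.degree[b] != 1:
                continue
            next_wid += 1
            if _carve_path(canvas, a, b, next_wid):
                n_anastomoses += 1
                used.update((a, b))

    n_endpoints = sum(1 for d in canvas.degree.values() if d <= 1)
    node_pixels = [p for p, d in canvas.degree.items() if d >= 3]
    # junction clusters == node pixels by construction (never adjacent)
    comp_has_node: dict = {}
    comp_pixels: dict = {}
    for p in canvas.degree:
        root = canvas._find(p)
        comp_pixels[root] = comp_pixels.get(root, 0) + 1
    for p in node_pixels:
        comp_has_node[canvas._find(p)] = True
    n_isolated = sum(
        1
        for root, cnt in comp_pixels.items()
        if cnt >= 2 and not comp_has_node.get(root, False)
    )
    truth = SyntheticGroundTruth(
        n_junctions=len(node_pixels),
        n_endpoints=n_endpoints,
        n_loops=canvas.n_loops,
        n_isolated=n_isolated,
        total_length=canvas.length,
        n_anastomoses=n_anastomoses,
        centerline=canvas.raster.copy(),
    )
    return canvas.raster, truth


def render_fundus(centerline: np.ndarray, spec: VascularTreeSpec) -> GrayscaleImage:
    """Draw dark vessels on a bright radially-graded background."""
    rng = np.random.default_rng([spec.seed & 0xFFFFFFFF, 17])
    size = centerline.shape[0]
    lo, hi = min(spec.vessel_width), max(spec.vessel_width)
    width = int(rng.integers(lo, hi + 1))
    vessels = centerline.copy()
    radius = (width - 1) // 2
    if radius > 0:
        rr = np.arange(-radius, radius + 1)
        disk = (rr[:, None] ** 2 + rr[None, :] ** 2) <= radius**2
        vessels = ndimage.binary_dilation(vessels, structure=disk)

    yy, xx = np.mgrid[:size, :size]
    cy = cx = (size - 1) / 2.0
    dist = np.hypot(yy - cy, xx - cx) / (size / 2.0)
    img = 0.85 - spec.background_gradient * dist**2
    img[vessels] = 0.25
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    return GrayscaleImage(
        pixels=np.clip(img, 0.0, 1.0),
        provenance=f"synthetic seed={spec.seed} width={width}",
    )


def generate_fundus(spec: VascularTreeSpec):
    """Topology + rendering in one call; returns (image, truth)."""
    centerline, truth = generate_topology(spec)
    return render_fundus(centerline, spec), truth


def recovery_analysis_config():
    """AnalysisConfig tuned for the default rendering regime (vessel width
    3-5 px, mild blur/noise): fine-scale Canny, enough closing to fuse the
    widest double contour, hole filling and spur pruning for the residual
    thinning artifacts, and whole-skeleton mesh counting so junction-free
    rings are measurable against ground-truth loops."""
    from .config import AnalysisConfig

    return AnalysisConfig(
        canny_sigma=1.0,
        closing_iterations=3,
        fill_hole_px=80,
        min_object_px=10,
        prune_spur_px=3.0,
        mesh_scope="all",
    )


DISJUNCTION_EFFECT = {
    "fragment_count": 2.5,
    "anastomosis_count": 0.0,
    "branch_prob": 1.5,
}
"""Multiplicative spec shifts mimicking the diabetic-like phenotype:
more disconnected fragments and extra branching, loss of closed loops."""


def apply_effect(spec: VascularTreeSpec, effect: dict) -> VascularTreeSpec:
    """Multiplicative parameter shifts; integer fields are rounded."""
    updates = {}
    for name, mult in effect.items():
        value = getattr(spec, name)
        if isinstance(value, int):
            updates[name] = int(round(value * mult))
        else:
            updates[name] = value * mult
    return replace(spec, **updates)


@dataclass
class Cohort:
    group_a: list  # list of (image, truth, spec)
    group_b: list


def generate_cohort(
    n_per_group: int,
    control_spec: VascularTreeSpec,
    effect: dict | None = None,
    seed: int = 0,
) -> Cohort:
    """Two seeded image groups; group B's spec carries the effect shifts.

    Per-image seeds derive from the master seed through SplitMix64, so a
    fixed master seed reproduces the cohort bit-identically.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    effect = effect if effect is not None else {}
    spec_b = apply_effect(control_spec, effect)
    groups = []
    for gi, base in enumerate((control_spec, spec_b)):
        members = []
        for i in range(n_per_group):
            s = replace(base, seed=derive_seed(seed, gi, i))
            image, truth = generate_fundus(s)
            members.append((image, truth, s))
        groups.append(members)
    return Cohort(group_a=groups[0], group_b=groups[1])
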