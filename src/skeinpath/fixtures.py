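"""Deterministic generators of test links: parametric knots, braid
closures, links, flips, connected sums and random protein-like chains.

Handedness anchor: the (2,3) torus-knot fixture produced by
:func:`make_fixture` is designated the *right-handed* trefoil; its
diagram writhe is +3 and every L/R label in the knot table flows from
this single choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .linkcore import (
    PolygonalLink,
    build_link,
    mirror_link,
    reverse_component,
    NonSimpleLinkError,
)

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "flips",
    "connected_sum",
    "split_union",
    "random_chain",
    "braid_link",
    "braid_gauss",
    "BRAID_WORDS",
    "oracle_gauss_code",
    "MINIMAL_TREFOIL",
    "MINIMAL_FIGURE_EIGHT",
    "minimal_stick_trefoil",
    "minimal_stick_figure_eight",
]


# ---------------------------------------------------------------------------
# braid closures
# ---------------------------------------------------------------------------
#
# Letters are nonzero ints: +i crosses strand slots (i-1, i) with the left
# strand passing over (a +1 crossing for upward strands), -i the mirror.

#: braid words for the shipped knot battery (trace closures, all strands
#: oriented alike). Positive words give the right-handed representative.
BRAID_WORDS = {
    "3_1": (2, [1, 1, 1]),
    "4_1": (3, [1, -2, 1, -2]),
    "5_1": (2, [1, 1, 1, 1, 1]),
    "5_2": (3, [1, 1, 1, 2, -1, 2]),
    "6_1": (4, [1, 1, 2, -1, -3, 2, -3]),
    "hopf+": (2, [1, 1]),
    "hopf-": (2, [-1, -1]),
}


def _braid_strand_passes(n_strands, word):
    slots = list(range(n_strands))
    passes = {s: [] for s in range(n_strands)}
    for k, g in enumerate(word):
        i = abs(g) - 1
        if not 0 <= i < n_strands - 1:
            raise ValueError(f"letter {g} out of range for {n_strands} strands")
        a, b = slots[i], slots[i + 1]
        sgn = 1 if g > 0 else -1
        if g > 0:
            passes[a].append((k, "o", sgn))
            passes[b].append((k, "u", sgn))
        else:
            passes[a].append((k, "u", sgn))
            passes[b].append((k, "o", sgn))
        slots[i], slots[i + 1] = b, a
    final_slot = {s: j for j, s in enumerate(slots)}
    return passes, final_slot


def braid_gauss(n_strands, word):
    """Oriented Gauss code (oracle input) of the braid's trace closure."""
    passes, final_slot = _braid_strand_passes(n_strands, word)
    comps, seen = [], set()
    for s0 in range(n_strands):
        if s0 in seen:
            continue
        comp, s = [], s0
        while s not in seen:
            seen.add(s)
            comp.extend(passes[s])
            s = final_slot[s]
        comps.append(comp)
    return comps


def braid_link(n_strands, word) -> PolygonalLink:
    """3D polygonal realisation of the braid's trace closure.

    Strands run along +y at integer x slots; each letter inserts a local
    over/under detour; closure arcs are routed around the left side at
    distinct heights so they add no diagram crossings.
    """
    slots = list(range(n_strands))
    pts = {s: [np.array([float(s), 0.0, 0.0])] for s in range(n_strands)}
    L = len(word)
    for k, g in enumerate(word):
        i = abs(g) - 1
        if not 0 <= i < n_strands - 1:
            raise ValueError(f"letter {g} out of range for {n_strands} strands")
        a, b = slots[i], slots[i + 1]
        y0, y1 = float(k), float(k + 1)
        # left strand a: slot i -> i+1 ; right strand b: slot i+1 -> i
        for s, x_in in ((a, float(i)), (b, float(i + 1))):
            if not np.allclose(pts[s][-1][:2], [x_in, y0]):
                pts[s].append(np.array([x_in, y0, 0.0]))
        over = a if g > 0 else b
        if over == a:
            pts[a].append(np.array([i + 0.5, y0 + 0.35, 1.0]))
        else:
            pts[b].append(np.array([i + 0.5, y0 + 0.35, 1.0]))
        pts[a].append(np.array([float(i + 1), y1, 0.0]))
        pts[b].append(np.array([float(i), y1, 0.0]))
        slots[i], slots[i + 1] = b, a
    final_slot = {s: j for j, s in enumerate(slots)}
    for s in range(n_strands):
        j = final_slot[s]
        if not np.allclose(pts[s][-1][:2], [float(j), float(L)]):
            pts[s].append(np.array([float(j), float(L), 0.0]))

    def closure_arc(j):
        h = 3.0 + j
        ytop = L + 1.0 + 0.2 * j
        ybot = -1.0 - 0.2 * j
        xleft = -2.0 - j
        return [
            np.array([float(j), ytop, h]),
            np.array([xleft, ytop, h]),
            np.array([xleft, ybot, h]),
            np.array([float(j), ybot, h]),
        ]

    points, separators, closed_flags = [], [], []
    seen = set()
    for s0 in range(n_strands):
        if s0 in seen:
            continue
        separators.append(len(points))
        s = s0
        while s not in seen:
            seen.add(s)
            points.extend(pts[s])
            points.extend(closure_arc(final_slot[s]))
            s = final_slot[s]
        closed_flags.append(True)
    return build_link(np.array(points), separators, closed_flags)


# ---------------------------------------------------------------------------
# parametric knots
# ---------------------------------------------------------------------------

def _detilt(pts):
    # fixed small tilt breaking the sampling symmetry of parametric curves,
    # so the native projection is regular (no vertex-on-edge coincidences)
    ax, ay = 0.021, 0.0137
    rx = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)], [0, np.sin(ax), np.cos(ax)]])
    ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0], [-np.sin(ay), 0, np.cos(ay)]])
    return pts @ (ry @ rx).T


def _torus_knot_points(p, q, n):
    # p winds around the axis, q around the tube: the standard projection
    # shows q crossings of equal sign for p = 2
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    r = 2.0 + np.cos(q * t)
    return _detilt(np.column_stack([r * np.cos(p * t), r * np.sin(p * t), -np.sin(q * t)]))


def _figure_eight_points(n):
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    r = 2.0 + np.cos(2 * t)
    return _detilt(np.column_stack([r * np.cos(3 * t), r * np.sin(3 * t), np.sin(4 * t)]))


def _square(side=1.0, origin=(0.0, 0.0, 0.0)):
    ox, oy, oz = origin
    return np.array(
        [
            [ox, oy, oz],
            [ox + side, oy, oz],
            [ox + side, oy + side, oz],
            [ox, oy + side, oz],
        ]
    )


#: hard-coded minimal stick representations ("sticky" forms); the 6-stick
#: trefoil is right-handed
MINIMAL_TREFOIL = np.array(
    [
        [0.244824, 0.606144, 0.607702],
        [0.091751, -0.593762, -0.584596],
        [-0.121563, 0.77949, -0.502216],
        [0.54886, -0.87495, 0.642329],
        [-0.493732, -0.231467, 0.041085],
        [0.205589, 0.266935, -0.384755],
    ]
)

MINIMAL_FIGURE_EIGHT = np.array(
    [
        [0.702187, -0.215124, -0.03938],
        [-0.647166, 0.428945, 0.005899],
        [-0.54853, -0.85461, -0.48242],
        [0.118154, 0.701692, 0.342047],
        [0.329712, -0.393048, -0.293383],
        [-0.771121, -0.396373, -0.091375],
        [0.33788, -0.195041, -0.822743],
    ]
)


def minimal_stick_trefoil() -> PolygonalLink:
    """6-stick trefoil (right-handed)."""
    return build_link(MINIMAL_TREFOIL, [0], [True])


def minimal_stick_figure_eight() -> PolygonalLink:
    """7-stick figure-eight."""
    return build_link(MINIMAL_FIGURE_EIGHT, [0], [True])


@dataclass(frozen=True)
class FixtureSpec:
    kind: str  # torus_knot | figure_eight | twist_knot | hopf | unlink | random_chain | braid
    n_points: int = 0
    seed: int = 0
    params: tuple = ()
    handedness: str = "R"


_STICK_MINIMUM = {
    "torus_knot": 30,
    "figure_eight": 40,
}


def make_fixture(spec: FixtureSpec) -> PolygonalLink:
    """Build the link described by ``spec``; bit-reproducible.

    Raises ValueError when the sampling is too coarse for the kind and
    the resulting polygon self-intersects.
    """
    kind = spec.kind
    try:
        if kind == "torus_knot":
            p, q = spec.params
            n = spec.n_points or 60
            if n < _STICK_MINIMUM["torus_knot"]:
                raise ValueError("torus knots need n >= 30 samples")
            pts = _torus_knot_points(p, q, n)
            link = build_link(pts, [0], [True])
        elif kind == "figure_eight":
            n = spec.n_points or 100
            if n < _STICK_MINIMUM["figure_eight"]:
                raise ValueError("figure-eight needs n >= 40 samples")
            link = build_link(_figure_eight_points(n), [0], [True])
        elif kind == "twist_knot":
            (k,) = spec.params
            name = {2: "4_1", 3: "5_2", 4: "6_1"}.get(k)
            if name is None:
                raise ValueError("twist knots are shipped for k in {2, 3, 4}")
            link = braid_link(*BRAID_WORDS[name])
        elif kind == "braid":
            name = spec.params[0]
            link = braid_link(*BRAID_WORDS[name])
        elif kind == "hopf":
            sign = spec.params[0] if spec.params else 1
            link = braid_link(*BRAID_WORDS["hopf+" if sign > 0 else "hopf-"])
        elif kind == "unlink":
            k = spec.params[0] if spec.params else 2
            pts = np.vstack([_square(origin=(2.5 * i, 0.0, 0.0)) for i in range(k)])
            link = build_link(pts, [4 * i for i in range(k)], [True] * k)
        elif kind == "random_chain":
            return random_chain(spec.n_points or 50, spec.seed)
        else:
            raise ValueError(f"unknown fixture kind {kind!r}")
    except NonSimpleLinkError as exc:
        raise ValueError(
            f"fixture {kind} self-intersects at this sampling; increase n_points"
        ) from exc
    if spec.handedness == "L":
        link = mirror_link(link)
    return link


def oracle_gauss_code(name: str):
    """Diagram (oracle) route for a battery entry: oriented Gauss code.

    Names: '3_1R', '3_1L', '4_1', '5_1R', ..., 'hopf+', 'unlink_2', 'U'.
    """
    if name == "U":
        return [[]]
    if name.startswith("unlink_"):
        return [[] for _ in range(int(name.split("_")[1]))]
    if name.startswith("hopf"):
        return braid_gauss(*BRAID_WORDS[name])
    base = name.rstrip("LR")
    hand = name[len(base):] or "R"
    n, word = BRAID_WORDS[base]
    if hand == "L":
        word = [-g for g in word]
    return braid_gauss(n, word)


# ---------------------------------------------------------------------------
# flips
# ---------------------------------------------------------------------------

def flips(link: PolygonalLink) -> list:
    """All mirror x orientation-reversal variants: 2^(c+1) links for c
    components, deduplicated, deterministic order."""
    out, seen = [], set()
    c = link.n_components
    for do_mirror in (False, True):
        base = mirror_link(link) if do_mirror else link
        for mask in product((False, True), repeat=c):
            var = base
            for ci, rev in enumerate(mask):
                if rev:
                    var = reverse_component(var, ci)
            key = np.round(var.points, 9).tobytes()
            if key not in seen:
                seen.add(key)
                out.append(var)
    return out


# ---------------------------------------------------------------------------
# connected sums and split unions
# ---------------------------------------------------------------------------

def _cycle_points_from_edge(link, edge_to_cut):
    """Points of a closed 1-component link reordered to start just after
    the cut edge and end at its tail."""
    pts = link.points
    n = len(pts)
    i = edge_to_cut  # edge i goes from point i to point (i+1) % n
    order = [(i + 1 + k) % n for k in range(n)]
    return pts[order]


def connected_sum(k1: PolygonalLink, k2: PolygonalLink, seed: int = 0, max_retries: int = 20) -> PolygonalLink:
    """Connected sum of two closed one-component links via edge excision
    and two bridging segments chosen collision-free."""
    from .linkcore import find_crossings, ensure_general_position

    if k1.n_components != 1 or k2.n_components != 1 or not (k1.closed_flags[0] and k2.closed_flags[0]):
        raise ValueError("connected_sum needs two closed single-component links")
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        a = k1.points - k1.points.mean(axis=0)
        b = k2.points - k2.points.mean(axis=0)
        if attempt:
            from scipy.spatial.transform import Rotation

            b = b @ Rotation.random(random_state=rng).as_matrix().T
        gap = 0.6 * (np.ptp(a[:, 0]) + np.ptp(b[:, 0])) + 1.0
        b = b + np.array([a[:, 0].max() - b[:, 0].min() + gap, 0.0, 0.0])
        # cut the rightmost edge of a and the leftmost edge of b
        na, nb = len(a), len(b)
        mid_a = (a + a[np.arange(1, na + 1) % na]) / 2
        mid_b = (b + b[np.arange(1, nb + 1) % nb]) / 2
        e1 = int(np.argmax(mid_a[:, 0]))
        e2 = int(np.argmin(mid_b[:, 0]))
        la = PolygonalLink(a, [0], [True])
        lb = PolygonalLink(b, [0], [True])
        pa = _cycle_points_from_edge(la, e1)  # starts at e1.to, ends e1.from
        pb = _cycle_points_from_edge(lb, e2)
        pts = np.vstack([pa, pb])
        try:
            cand = build_link(pts, [0], [True])
        except NonSimpleLinkError:
            continue
        # the two bridges are the edges (len(pa)-1 -> len(pa)) and the
        # closing edge; neither may cross anything in projection
        try:
            cand = ensure_general_position(cand, seed=seed + attempt)
            crossings = find_crossings(cand)
        except Exception:
            continue
        bridge_ids = {len(pa) - 1, len(pts) - 1}
        if any(c.under_edge in bridge_ids or c.over_edge in bridge_ids for c in crossings):
            continue
        return cand
    raise RuntimeError("connected_sum: no collision-free bridge found")


def split_union(l1: PolygonalLink, l2: PolygonalLink) -> PolygonalLink:
    """Disjoint placement of two links, components merged."""
    a = l1.points - l1.points.mean(axis=0)
    b = l2.points - l2.points.mean(axis=0)
    gap = 0.6 * (np.ptp(a[:, 0]) + np.ptp(b[:, 0])) + 1.0
    b = b + np.array([a[:, 0].max() - b[:, 0].min() + gap, 0.0, 0.0])
    pts = np.vstack([a, b])
    seps = list(l1.separators) + [s + len(a) for s in l2.separators]
    flags = list(l1.closed_flags) + list(l2.closed_flags)
    return build_link(pts, seps, flags)


def deep_open_trefoil(tail_points: int = 15, n: int = 60, hand: str = "R") -> PolygonalLink:
    """Open protein-like trefoil: the torus-knot polygon opened at one
    vertex, rescaled to ~3.8 A bonds, with straight radially outgoing
    tails appended at both ends (the knotted core sits far from the
    termini, so any closure policy sees the same knot)."""
    closed = make_fixture(FixtureSpec("torus_knot", n, params=(2, 3), handedness=hand))
    pts = closed.points
    edge = np.linalg.norm(np.diff(pts, axis=0), axis=1).max()
    pts = pts * (3.8 / edge)  # keep every virtual bond under the gap threshold
    centroid = pts.mean(axis=0)

    def tail(p, nxt):
        d = p - centroid
        d = d / np.linalg.norm(d)
        return [p + 3.8 * (k + 1) * d for k in range(tail_points)]

    head = tail(pts[0], pts[1])[::-1]
    foot = tail(pts[-1], pts[-2])
    allpts = np.vstack([head, pts, foot])
    return build_link(allpts, [0], [False])


# ---------------------------------------------------------------------------
# random protein-like chains
# ---------------------------------------------------------------------------

STEP_A = 3.8  # virtual Calpha-Calpha bond, Angstrom
MIN_NONNEIGHBOR_A = 3.0


def random_chain(n: int, seed: int, style: str = "walk") -> PolygonalLink:
    """Open single-component chain with fixed 3.8 A steps and excluded
    volume (non-neighbour distance >= 3.0 A); fully seeded."""
    if n < 4:
        raise ValueError("need n >= 4")
    if style not in ("walk", "helix_mix"):
        raise ValueError(f"unknown style {style!r}")
    rng = np.random.default_rng(seed)
    for restart in range(40):
        pts = [np.zeros(3)]
        ok = True
        helix_phase = 0
        helix_frame = None
        while len(pts) < n and ok:
            placed = False
            for _ in range(120):
                if style == "helix_mix" and helix_phase > 0 and helix_frame is not None:
                    axis, ref, angle0 = helix_frame
                    ang = angle0 + np.deg2rad(100.0) * helix_phase
                    radial = np.cos(ang) * ref + np.sin(ang) * np.cross(axis, ref)
                    step = 1.5 * axis + 2.3 * radial - (pts[-1] - helix_frame_origin)
                    d = step / np.linalg.norm(step) * STEP_A
                else:
                    v = rng.normal(size=3)
                    d = v / np.linalg.norm(v) * STEP_A
                cand = pts[-1] + d
                if len(pts) >= 2:
                    dists = np.linalg.norm(np.array(pts[:-1]) - cand, axis=1)
                    if dists.min() < MIN_NONNEIGHBOR_A:
                        if style == "helix_mix":
                            helix_phase = 0
                        continue
                pts.append(cand)
                placed = True
                break
            if not placed:
                ok = False
            if style == "helix_mix":
                if helix_phase > 0:
                    helix_phase += 1
                    if helix_phase > 8:
                        helix_phase = 0
                elif rng.random() < 0.15:
                    axis = rng.normal(size=3)
                    axis /= np.linalg.norm(axis)
                    ref = np.cross(axis, rng.normal(size=3))
                    ref /= np.linalg.norm(ref)
                    helix_frame = (axis, ref, rng.uniform(0, 2 * np.pi))
                    helix_frame_origin = pts[-1].copy()
                    helix_phase = 1
        if ok:
            return build_link(np.array(pts), [0], [False])
    raise RuntimeError(f"random_chain placement failed for n={n}, seed={seed}")
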