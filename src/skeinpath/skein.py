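"""Geometric construction of Conway skein triples on the 3D structure.

For a chosen crossing the under and over edges are cut at the crossing
and a *clean quadrilateral* is grown around it (vertices on the four cut
edges, its projection containing no other edge of the diagram).  The
switch configuration reroutes the under strand through a perturbed point
above the overpass; the zero configuration reconnects the strands
through two opposite sides of the rotated quadrilateral, respecting
orientation.  Each construction is validated against the original
diagram: the switch changes exactly one crossing (now an overpass), the
smoothing removes exactly one, everything else is preserved.

The skein tree is built by recursively switching/smoothing candidate
crossings (those first met as underpass along the traversal order, which
guarantees termination) with MSR reduction at every node.
"""

from __future__ import annotations

import json
from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np

from .linkcore import (
    PolygonalLink,
    Crossing2D,
    ensure_general_position,
    find_crossings,
    diagram_gauss_code,
    is_regular,
    segment_hits,
    EPS_REGULAR,
    check_simple,
    NonSimpleLinkError,
)
from .msr import msr_reduce

__all__ = [
    "QuadParams",
    "StatusTable",
    "SkeinNode",
    "SkeinTree",
    "SkeinConstructionError",
    "build_clean_quadrilateral",
    "xclean",
    "rotate_quadrilateral",
    "two_side_replacement_check",
    "make_switch_config",
    "make_zero_config",
    "select_crossing",
    "build_skein_tree",
    "audit_capture",
    "MAX_HALVINGS",
]

MAX_HALVINGS = 60
MAX_TREE_DEPTH = 64
ALPHA_INIT = 0.9

#: cut indices, fixed order
U_BACK, U_FWD, O_BACK, O_FWD = 0, 1, 2, 3


class SkeinConstructionError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# audit instrumentation (used by the acceptance suite)
# ---------------------------------------------------------------------------

class _Audit:
    def __init__(self):
        self.alpha_sequences = []
        self.switch_checks = []  # (one_crossing_changed, is_overpass)
        self.triples = []  # (epsilon, P_plus, P_minus, P_zero) filled by homfly


_audit = None


@contextmanager
def audit_capture():
    """Collect construction evidence (alpha sequences, switch checks)."""
    global _audit
    prev = _audit
    _audit = _Audit()
    try:
        yield _audit
    finally:
        _audit = prev


def _audit_obj():
    return _audit


# ---------------------------------------------------------------------------
# quadrilateral machinery
# ---------------------------------------------------------------------------

@dataclass
class QuadParams:
    """Clean quadrilateral around a crossing.

    ``t[i]`` in (0, 1] positions the vertex of cut i (U_BACK, U_FWD,
    O_BACK, O_FWD) between the crossing (t=0) and the respective edge
    endpoint (t=1); ``order`` lists the cut indices in counterclockwise
    cyclic order around the crossing.
    """

    crossing: Crossing2D
    t: np.ndarray  # (4,)
    ends3d: np.ndarray  # (4, 3) cut-edge far endpoints
    x3d: np.ndarray  # (4, 3) the two lifted crossing points, per cut
    order: list  # cyclic order of cut indices

    def vertex(self, i: int, shrink: float = 1.0) -> np.ndarray:
        """Lifted vertex of cut i at the current parameter; ``shrink``
        pulls it toward the crossing (cleanness is preserved: the shrunk
        quadrilateral is contained in the clean one)."""
        return self.x3d[i] + shrink * self.t[i] * (self.ends3d[i] - self.x3d[i])

    def vertices_cyclic(self) -> np.ndarray:
        return np.array([self.vertex(i) for i in self.order])


@dataclass
class StatusTable:
    """n x 2 side-intersection statuses; row i = (entering, leaving) of
    vertex i.  The leaving entry of row i equals the entering entry of
    row i+1 (shared side, cyclically)."""

    rows: np.ndarray  # (n, 2) of 0/1

    def clean(self) -> bool:
        return not self.rows.any()


def _cut_data(link, crossing):
    """Endpoint/crossing-point data of the four cut edges."""
    es = link.edges()
    eu, eo = es[crossing.under_edge], es[crossing.over_edge]
    A1, A2 = link.points[eu.from_idx], link.points[eu.to_idx]
    B1, B2 = link.points[eo.from_idx], link.points[eo.to_idx]
    xu = A1 + crossing.under_param * (A2 - A1)  # lifted under point
    xo = B1 + crossing.over_param * (B2 - B1)  # lifted over point
    ends = np.array([A1, A2, B1, B2])
    x3d = np.array([xu, xu, xo, xo])
    return ends, x3d


def _cyclic_order(ends, x3d):
    xy = np.asarray(ends)[:, :2] - np.asarray(x3d)[:, :2]
    ang = np.arctan2(xy[:, 1], xy[:, 0])
    return list(np.argsort(ang))


def _side_hit_count(link, p, q, skip_edges):
    """Number of link-edge intersections interior to side (p, q)."""
    ok, hits = segment_hits(link, p, q, skip_edges)
    if not ok:
        return None  # degenerate: treat as dirty
    return len(hits)


def xclean(polygon, link, status: StatusTable, touched_vertex_indices, skip_edges=frozenset()):
    """Recompute side statuses for the sides adjacent to touched
    vertices; returns (clean, updated StatusTable).

    ``polygon`` is an (n, 3) vertex array in cyclic order (lifted points;
    only the projection matters here).
    """
    n = len(polygon)
    rows = status.rows.copy()
    sides = set()
    for v in touched_vertex_indices:
        sides.add(v % n)  # side leaving vertex v
        sides.add((v - 1) % n)  # side entering vertex v
    for s in sides:
        p, q = polygon[s], polygon[(s + 1) % n]
        cnt = _side_hit_count(link, p, q, skip_edges)
        val = 1 if (cnt is None or cnt > 0) else 0
        rows[s, 1] = val  # leaving vertex s
        rows[(s + 1) % n, 0] = val  # entering vertex s+1
    table = StatusTable(rows)
    return table.clean(), table


def _vertex_inside_poly(link, polygon2d, exclude_idx):
    """Any link vertex strictly inside the projected polygon (crossing-
    number test)?"""
    pts = link.points[:, :2]
    mask = np.ones(len(pts), dtype=bool)
    for i in exclude_idx:
        mask[i] = False
    P = np.asarray(polygon2d)
    n = len(P)
    pts = pts[mask]
    if not len(pts):
        return False
    # points on the polygon boundary (e.g. cut vertices at t=1 coincide
    # with link vertices) are not "swallowed"
    tol = EPS_REGULAR * link.bbox_diag()
    on_boundary = np.zeros(len(pts), dtype=bool)
    for i in range(n):
        a, b = P[i], P[(i + 1) % n]
        ab = b - a
        L2 = float(ab @ ab) or 1e-300
        tpar = np.clip(((pts - a) @ ab) / L2, 0.0, 1.0)
        dist = np.linalg.norm(pts - (a + tpar[:, None] * ab), axis=1)
        on_boundary |= dist < tol
    pts = pts[~on_boundary]
    if not len(pts):
        return False
    inside = np.zeros(len(pts), dtype=bool)
    x, y = pts[:, 0], pts[:, 1]
    for i in range(n):
        x1, y1 = P[i]
        x2, y2 = P[(i + 1) % n]
        crosses = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (x < np.where(crosses, xint, np.inf))
    return bool(inside.any())


def _quad_clean(link, quad, skip_edges, vertices=None):
    poly = quad.vertices_cyclic() if vertices is None else vertices
    status = StatusTable(np.zeros((4, 2), dtype=int))
    clean, status = xclean(poly, link, status, range(4), skip_edges)
    if not clean:
        return False, status
    if _vertex_inside_poly(link, poly[:, :2], exclude_idx=[]):
        return False, status
    return True, status


def build_clean_quadrilateral(link: PolygonalLink, crossing: Crossing2D) -> QuadParams:
    """Grow the clean quadrilateral: start with full cut edges (t = 1)
    and repeatedly halve the parameter of the longest dirty cut edge."""
    ends, x3d = _cut_data(link, crossing)
    order = _cyclic_order(ends, x3d)
    skip = frozenset({crossing.under_edge, crossing.over_edge})
    quad = QuadParams(crossing, np.ones(4), ends, x3d, order)
    for _ in range(MAX_HALVINGS):
        poly = quad.vertices_cyclic()
        status = StatusTable(np.zeros((4, 2), dtype=int))
        clean, status = xclean(poly, link, status, range(4), skip)
        inside = _vertex_inside_poly(link, poly[:, :2], exclude_idx=[])
        if clean and not inside:
            return quad
        # dirty cuts: a cut is dirty when a side adjacent to its vertex
        # has intersections; a swallowed vertex dirties every cut
        cutlen = np.array(
            [
                quad.t[i] * np.linalg.norm((ends[i] - x3d[i])[:2])
                for i in range(4)
            ]
        )
        dirty = set()
        if inside:
            dirty = {0, 1, 2, 3}
        else:
            for pos, cut in enumerate(order):
                if status.rows[pos].any():
                    dirty.add(cut)
        longest = max(dirty, key=lambda i: cutlen[i])
        quad.t[longest] /= 2.0
    raise SkeinConstructionError(
        "could not build a clean quadrilateral (pathological clustering)"
    )


def rotate_quadrilateral(link: PolygonalLink, quad: QuadParams, crossing: Crossing2D):
    """Rotate the quadrilateral's projected vertices about the crossing
    point; the initial angle is the minimum angle between the two
    projected crossing-edge directions, with the sign chosen so no side
    sweeps across the other edge's original position; halve until clean.

    Returns (rotated vertex array in cut order (4, 3), theta).
    """
    p0s, p1s, comp, es = link.edge_arrays()
    du = (p1s - p0s)[crossing.under_edge][:2]
    do = (p1s - p0s)[crossing.over_edge][:2]
    phi_u = np.arctan2(du[1], du[0])
    phi_o = np.arctan2(do[1], do[0])
    g = (phi_o - phi_u) % np.pi
    theta0 = min(g, np.pi - g)
    # rotating CCW by g lands on the over line; go the other way
    sign = -1.0 if g <= np.pi / 2 else 1.0
    theta = sign * theta0
    skip = frozenset({crossing.under_edge, crossing.over_edge})
    x2d = np.array(crossing.xy)
    base = np.array([quad.vertex(i, shrink=0.75) for i in range(4)])
    for _ in range(MAX_HALVINGS):
        if abs(theta) < 1e-12:
            raise SkeinConstructionError("rotation angle underflow")
        c, s = np.cos(theta), np.sin(theta)
        R = np.array([[c, -s], [s, c]])
        rot = base.copy()
        rot[:, :2] = (base[:, :2] - x2d) @ R.T + x2d
        poly = rot[list(quad.order)]
        clean, _ = _quad_clean(link, quad, skip, vertices=poly)
        # sides must not be parallel to either original edge
        ok_par = True
        for i in range(4):
            sd = poly[(i + 1) % 4, :2] - poly[i, :2]
            for dref in (du, do):
                if abs(sd[0] * dref[1] - sd[1] * dref[0]) <= 1e-9 * np.linalg.norm(sd) * np.linalg.norm(dref):
                    ok_par = False
        if clean and ok_par:
            return rot, theta
        theta /= 2.0
    raise SkeinConstructionError("could not rotate quadrilateral clean")


def two_side_replacement_check(
    link: PolygonalLink,
    original_cut_edges,
    replacement_path,
    dividing_segment,
    skip_edges=frozenset(),
) -> bool:
    """True iff the dividing segment has no projected intersections with
    the remainder and the replacement path crosses the same edges as the
    original cut edges, in the same order and with identical statuses."""
    ok, hits = segment_hits(link, dividing_segment[0], dividing_segment[1], skip_edges)
    if not ok or hits:
        return False

    def pattern(segments):
        pat = []
        for p, q in segments:
            ok, hits = segment_hits(link, p, q, skip_edges)
            if not ok:
                return None
            pat.extend((e, st) for _, e, st in hits)
        return pat

    orig = pattern(original_cut_edges)
    repl = pattern(list(zip(replacement_path, replacement_path[1:])))
    return orig is not None and repl is not None and orig == repl


# ---------------------------------------------------------------------------
# diagram bookkeeping helpers
# ---------------------------------------------------------------------------

def _crossing_key(c, scale):
    return (round(c.xy[0] / scale, 7), round(c.xy[1] / scale, 7))


def _diagram_map(link, crossings=None, scale=None):
    if scale is None:
        scale = link.bbox_diag()
    if crossings is None:
        crossings = find_crossings(link)
    return {
        _crossing_key(c, scale): (c.oriented_sign,) for c in crossings
    }, crossings


# ---------------------------------------------------------------------------
# skein configurations
# ---------------------------------------------------------------------------

def _replace_edge_with_path(link, edge_id, inner_points):
    """New link with edge ``edge_id`` (from->to) subdivided through the
    given interior points."""
    es = link.edges()
    e = es[edge_id]
    pts = link.points
    inner = np.asarray(inner_points, dtype=float)
    if e.to_idx == e.from_idx + 1:
        insert_at = e.from_idx + 1
    else:
        # closing edge of a closed component: append at component end
        insert_at = link.component_range(e.component)[1]
    new_pts = np.vstack([pts[:insert_at], inner, pts[insert_at:]])
    shift = len(inner)
    seps = [s if s < insert_at else s + shift for s in link.separators]
    return PolygonalLink(new_pts, seps, list(link.closed_flags))


def make_switch_config(link: PolygonalLink, crossing: Crossing2D) -> PolygonalLink:
    """The crossing-switch member of the triple (L-/+ of an L+/- node).

    The under edge is rerouted through the clean-quadrilateral vertices
    and a perturbed copy of the point-reflection of the under crossing
    point through the over crossing point; the perturbation factor alpha
    starts at 0.9 and converges monotonically to 1 until the rerouted
    strand crosses the other edge exactly once, as an overpass, leaving
    every other crossing untouched.
    """
    quad = build_clean_quadrilateral(link, crossing)
    ends, x3d = _cut_data(link, crossing)
    xu, xo = x3d[U_BACK], x3d[O_BACK]
    q1 = quad.vertex(U_BACK, shrink=0.75)
    q2 = quad.vertex(U_FWD, shrink=0.75)
    du2 = (ends[U_FWD] - x3d[U_FWD])[:2]
    du2 = du2 / np.linalg.norm(du2)
    d1 = np.linalg.norm((q1 - xu)[:2])
    d2 = np.linalg.norm((q2 - xu)[:2])
    delta = 0.25 * min(d1, d2)

    scale = link.bbox_diag()
    orig_map, orig_crossings = _diagram_map(link)
    target_key = _crossing_key(crossing, scale)

    alpha = ALPHA_INIT
    alphas = [alpha]
    # reflection height, floored so nearly-planar crossings (tiny z gap)
    # still admit an overpass within the halving budget
    dz = max(xo[2] - xu[2], 0.02 * scale)
    for _ in range(MAX_HALVINGS):
        p_xy = np.array(crossing.xy) + delta * du2
        p = np.array([p_xy[0], p_xy[1], xo[2] + alpha * dz])
        cand = _replace_edge_with_path(link, crossing.under_edge, [q1, p, q2])
        ok, reason = _validate_switch(cand, link, orig_map, target_key, scale)
        if ok:
            if _audit is not None:
                _audit.alpha_sequences.append(list(alphas))
                _audit.switch_checks.append((True, True))
            return cand
        if 1.0 - alpha < 1e-12:
            raise SkeinConstructionError(
                f"switch construction failed with alpha -> 1 ({reason})"
            )
        alpha = (1.0 + alpha) / 2.0
        alphas.append(alpha)
        delta /= 2.0
    raise SkeinConstructionError("switch construction exceeded halving budget")


def _validate_switch(cand, link, orig_map, target_key, scale):
    try:
        check_simple(cand)
    except NonSimpleLinkError:
        return False, "not simple"
    if not is_regular(cand):
        return False, "projection not regular"
    new_map, _ = _diagram_map(cand, scale=scale)
    if set(new_map) != set(orig_map):
        return False, "crossing set changed"
    for k in orig_map:
        if k == target_key:
            # the switch negates the oriented sign (over/under swap)
            if new_map[k][0] != -orig_map[k][0]:
                return False, "target crossing did not switch"
        elif new_map[k] != orig_map[k]:
            return False, "crossing data changed unexpectedly"
    return True, None


def make_zero_config(link: PolygonalLink, crossing: Crossing2D, quad_rot=None) -> PolygonalLink:
    """The oriented smoothing L0: the two crossing edges are replaced by
    the reconnection through two opposite sides of the rotated clean
    quadrilateral; the component count goes up by one for a
    self-crossing, down by one when the edges belong to two (closed)
    components."""
    quad = build_clean_quadrilateral(link, crossing)
    if quad_rot is None:
        rot, theta = rotate_quadrilateral(link, quad, crossing)
    else:
        rot, theta = quad_rot, None

    skip = frozenset({crossing.under_edge, crossing.over_edge})
    es = link.edges()
    eu, eo = es[crossing.under_edge], es[crossing.over_edge]
    A1 = link.points[eu.from_idx]
    A2 = link.points[eu.to_idx]
    B1 = link.points[eo.from_idx]
    B2 = link.points[eo.to_idx]
    v = np.array([quad.vertex(i, shrink=0.75) for i in range(4)])

    n_orig_cross = len(find_crossings(link))
    for _ in range(MAX_HALVINGS):
        W = rot
        ok = (
            two_side_replacement_check(
                link,
                [(A1, v[U_BACK])],
                [A1, W[U_BACK]],
                (W[U_BACK], W[O_FWD]),
                skip,
            )
            and two_side_replacement_check(
                link,
                [(v[O_FWD], B2)],
                [W[O_FWD], B2],
                (W[U_BACK], W[O_FWD]),
                skip,
            )
            and two_side_replacement_check(
                link,
                [(B1, v[O_BACK])],
                [B1, W[O_BACK]],
                (W[O_BACK], W[U_FWD]),
                skip,
            )
            and two_side_replacement_check(
                link,
                [(v[U_FWD], A2)],
                [W[U_FWD], A2],
                (W[O_BACK], W[U_FWD]),
                skip,
            )
        )
        cand = None
        if ok:
            cand = _splice_zero(link, crossing, W)
            if cand is not None:
                try:
                    check_simple(cand)
                except NonSimpleLinkError:
                    cand = None
            if cand is not None and not is_regular(cand):
                cand = None
            if cand is not None and len(find_crossings(cand)) != n_orig_cross - 1:
                cand = None
        if cand is not None:
            expected = link.n_components + (1 if eu.component == eo.component else -1)
            if cand.n_components != expected:
                raise SkeinConstructionError("component count invariant violated")
            return cand
        if theta is None:
            raise SkeinConstructionError("supplied rotated quadrilateral rejected")
        theta /= 2.0
        if abs(theta) < 1e-12:
            raise SkeinConstructionError("rotation angle underflow in smoothing")
        c, s = np.cos(theta), np.sin(theta)
        R = np.array([[c, -s], [s, c]])
        base = np.array([quad.vertex(i, shrink=0.75) for i in range(4)])
        rot = base.copy()
        rot[:, :2] = (base[:, :2] - np.array(crossing.xy)) @ R.T + np.array(crossing.xy)
    raise SkeinConstructionError("smoothing construction exceeded halving budget")


def _splice_zero(link, crossing, W):
    """Point-list surgery for the oriented smoothing."""
    es = link.edges()
    eu, eo = es[crossing.under_edge], es[crossing.over_edge]
    cu, co = eu.component, eo.component
    pts = link.points
    chord_a = [W[U_BACK], W[O_FWD]]  # tail of u -> head of o
    chord_b = [W[O_BACK], W[U_FWD]]  # tail of o -> head of u

    def comp_indices(c):
        a, b = link.component_range(c)
        return list(range(a, b))

    new_comps = []  # (points list, closed flag) replacing the touched comps
    if cu == co:
        c = cu
        a, b = link.component_range(c)
        k = b - a
        closed = link.closed_flags[c]
        iu = eu.from_idx - a
        io = eo.from_idx - a
        if closed:
            def arc(frm, to):  # inclusive cyclic walk frm..to
                out = [frm]
                while out[-1] != to:
                    out.append((out[-1] + 1) % k)
                return [pts[a + j] for j in out]

            loop1 = arc((io + 1) % k, iu) + chord_a  # B2..A1 + chord
            loop2 = arc((iu + 1) % k, io) + chord_b  # A2..B1 + chord
            new_comps = [(loop1, True), (loop2, True)]
        else:
            first, second = (iu, io) if iu < io else (io, iu)
            if iu < io:
                outer = (
                    [pts[a + j] for j in range(0, iu + 1)]
                    + chord_a
                    + [pts[a + j] for j in range(io + 1, k)]
                )
                loop = [pts[a + j] for j in range(iu + 1, io + 1)] + chord_b
            else:
                outer = (
                    [pts[a + j] for j in range(0, io + 1)]
                    + chord_b
                    + [pts[a + j] for j in range(iu + 1, k)]
                )
                loop = [pts[a + j] for j in range(io + 1, iu + 1)] + chord_a
            new_comps = [(outer, False), (loop, True)]
    else:
        if not (link.closed_flags[cu] and link.closed_flags[co]):
            raise SkeinConstructionError(
                "smoothing between components requires closed components"
            )
        au, bu = link.component_range(cu)
        ao, bo = link.component_range(co)
        ku, ko = bu - au, bo - ao
        iu = eu.from_idx - au
        io = eo.from_idx - ao
        rot_u = [pts[au + (iu + 1 + j) % ku] for j in range(ku)]  # A2..A1
        rot_o = [pts[ao + (io + 1 + j) % ko] for j in range(ko)]  # B2..B1
        merged = rot_u + chord_a + rot_o + chord_b
        new_comps = [(merged, True)]

    touched = {cu, co}
    points, seps, flags = [], [], []
    inserted = False
    for c in range(link.n_components):
        if c in touched:
            if inserted:
                continue
            inserted = True
            for plist, closed in new_comps:
                seps.append(len(points))
                points.extend(plist)
                flags.append(closed)
        else:
            a, b = link.component_range(c)
            seps.append(len(points))
            points.extend(pts[a:b])
            flags.append(link.closed_flags[c])
    try:
        return PolygonalLink(np.array(points), seps, flags)
    except Exception:
        return None


# ---------------------------------------------------------------------------
# crossing selection and the skein tree
# ---------------------------------------------------------------------------

def _first_under_candidates(link, crossings=None):
    """Crossings first met as underpass along the traversal order."""
    if crossings is None:
        crossings = find_crossings(link)
    if not crossings:
        return []
    code = diagram_gauss_code(link)
    met_over = set()
    out = []
    for comp in code:
        for cid, ou, sign in comp:
            if ou == "o":
                met_over.add(cid)
            elif cid not in met_over and cid not in {c for c, _ in out}:
                out.append((cid, crossings[cid]))
    return out


def select_crossing(link: PolygonalLink, strategy: str = "greedy"):
    """Next crossing to process, or None for a descending diagram."""
    crossings = find_crossings(link)
    cands = _first_under_candidates(link, crossings)
    if not cands:
        return None
    if strategy == "fixed":
        return cands[0][1]
    if strategy != "greedy":
        raise ValueError(f"unknown strategy {strategy!r}")
    best = None
    for cid, c in cands:
        try:
            switched = make_switch_config(link, c)
            reduced, _ = msr_reduce(switched)
        except SkeinConstructionError:
            continue  # unusable candidate; node is re-perturbed if all fail
        key = (reduced.n_points, c.under_edge)
        if best is None or key < best[0]:
            best = (key, c)
    if best is None:
        raise SkeinConstructionError("no switchable candidate at this node")
    return best[1]


@dataclass
class SkeinNode:
    link: PolygonalLink
    epsilon: int = 0  # skein sign of the switched crossing; 0 at leaves
    children: tuple | None = None  # (switch_child, zero_child)
    n_components: int | None = None
    weight: object = None
    node_id: int = 0


@dataclass
class SkeinTree:
    root: SkeinNode
    g: int = 0  # levels (generations)
    nu: int = 0  # node count

    def nodes(self):
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            if n.children:
                stack.extend(n.children)
        return out

    def to_json(self) -> str:
        items = []
        for n in self.nodes():
            items.append(
                {
                    "id": n.node_id,
                    "points": n.link.n_points,
                    "epsilon": n.epsilon,
                    "children": [c.node_id for c in n.children] if n.children else None,
                    "components": n.n_components,
                }
            )
        return json.dumps({"g": self.g, "nu": self.nu, "nodes": items}, indent=1)


def build_skein_tree(link: PolygonalLink, strategy: str = "greedy", seed: int = 0) -> SkeinTree:
    """Root = MSR-reduced input; recursively attach switch and zero
    children (each MSR-reduced) until every branch is descending."""
    counter = [0]

    def new_node(lnk):
        n = SkeinNode(lnk, node_id=counter[0])
        counter[0] += 1
        return n

    reduced, _ = msr_reduce(ensure_general_position(link, seed))
    root = new_node(reduced)
    max_depth = [0]

    def grow(node, depth):
        if depth > MAX_TREE_DEPTH:
            raise SkeinConstructionError("skein recursion exceeded depth budget")
        max_depth[0] = max(max_depth[0], depth)
        # a numerically awkward projection (crossing grazing a vertex) can
        # defeat the quadrilateral constructions: re-perturb with a fresh
        # rotation and re-reduce, deterministically
        last_exc = None
        for attempt in range(6):
            if attempt:
                from .linkcore import rotate_link

                reperturbed = rotate_link(node.link, seed + 104729 * attempt + depth)
                node.link, _ = msr_reduce(reperturbed, seed=seed + attempt)
            try:
                c = select_crossing(node.link, strategy)
                if c is None:
                    node.n_components = node.link.n_components
                    return
                node.epsilon = c.oriented_sign
                sw_link, _ = msr_reduce(make_switch_config(node.link, c))
                zr_link, _ = msr_reduce(make_zero_config(node.link, c))
                break
            except SkeinConstructionError as exc:
                last_exc = exc
        else:
            raise SkeinConstructionError(
                f"node construction failed after re-perturbations: {last_exc}"
            )
        sw, zr = new_node(sw_link), new_node(zr_link)
        node.children = (sw, zr)
        grow(sw, depth + 1)
        grow(zr, depth + 1)

    grow(root, 0)
    return SkeinTree(root, g=max_depth[0], nu=counter[0])
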