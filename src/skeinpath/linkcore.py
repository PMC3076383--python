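"""Geometric data model for polygonal links.

A polygonal link is an ordered set of 3D points partitioned into
components, each of which is an open or closed polygonal path.  All
topological information is read off the *standard projection* (drop z):
crossings between non-adjacent edges, their over/under assignment from
the z coordinates of the lifted intersection points, and oriented signs
by the right-hand convention (approach the crossing along the underpass
in the direction of orientation; the sign is +1 when the overpass runs
left to right).

Conventions
-----------
* indexing is 0-based; components are half-open index ranges given by
  ``separators`` (start index of each component);
* edges are oriented along traversal; a closed component has one extra
  edge joining its last point back to its first;
* geometric predicates use a relative tolerance; projections that put a
  vertex on a non-incident edge, produce near-coincident crossings or
  parallel-overlapping edges are *non-regular* and must be repaired with
  :func:`ensure_general_position`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Point3",
    "Edge",
    "Crossing2D",
    "PolygonalLink",
    "NonSimpleLinkError",
    "NonRegularProjectionError",
    "GeneralPositionError",
    "build_link",
    "ensure_general_position",
    "find_crossings",
    "mirror_link",
    "reverse_component",
    "intersection_matrix",
    "writhe",
    "read_coords",
    "write_coords",
    "loads_coords",
    "dumps_coords",
]

#: relative epsilon for intersection / orientation predicates
EPS_PRED = 1e-9
#: crossings closer than this (relative to the bbox diagonal) to a vertex
#: or to each other make a projection non-regular
EPS_REGULAR = 1e-7
MAX_ROTATION_ATTEMPTS = 50

Point3 = np.ndarray  # shape (3,) float array


class NonSimpleLinkError(ValueError):
    """The 3D polygonal path self-intersects away from shared endpoints."""

    def __init__(self, msg, edge_pair=None):
        super().__init__(msg)
        self.edge_pair = edge_pair


class NonRegularProjectionError(ValueError):
    """The standard projection violates a regularity condition."""


class GeneralPositionError(RuntimeError):
    """No regular projection was found within the rotation budget."""


@dataclass(frozen=True)
class Edge:
    edge_id: int
    from_idx: int
    to_idx: int
    component: int


@dataclass(frozen=True)
class Crossing2D:
    under_edge: int
    over_edge: int
    xy: tuple
    oriented_sign: int
    under_param: float
    over_param: float


@dataclass
class PolygonalLink:
    points: np.ndarray  # (n, 3)
    separators: list  # start index of each component
    closed_flags: list  # per-component bool

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.separators = list(self.separators)
        self.closed_flags = list(self.closed_flags)

    # -- component bookkeeping -------------------------------------------
    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_components(self) -> int:
        return len(self.separators)

    def component_range(self, c: int) -> tuple:
        """Half-open point-index range [start, stop) of component ``c``."""
        start = self.separators[c]
        stop = self.separators[c + 1] if c + 1 < len(self.separators) else self.n_points
        return start, stop

    def component_points(self, c: int) -> np.ndarray:
        a, b = self.component_range(c)
        return self.points[a:b]

    def component_of_point(self, idx: int) -> int:
        for c in range(self.n_components):
            a, b = self.component_range(c)
            if a <= idx < b:
                return c
        raise IndexError(idx)

    def edges(self) -> list:
        """Oriented edges in traversal order (closing edge last per component)."""
        out = []
        eid = 0
        for c in range(self.n_components):
            a, b = self.component_range(c)
            for i in range(a, b - 1):
                out.append(Edge(eid, i, i + 1, c))
                eid += 1
            if self.closed_flags[c]:
                out.append(Edge(eid, b - 1, a, c))
                eid += 1
        return out

    def edge_arrays(self):
        """(starts, ends, component-id) coordinate arrays for all edges."""
        es = self.edges()
        frm = np.array([e.from_idx for e in es], dtype=int)
        to = np.array([e.to_idx for e in es], dtype=int)
        comp = np.array([e.component for e in es], dtype=int)
        return self.points[frm], self.points[to], comp, es

    def copy(self) -> "PolygonalLink":
        return PolygonalLink(self.points.copy(), list(self.separators), list(self.closed_flags))

    def bbox_diag(self) -> float:
        span = self.points.max(axis=0) - self.points.min(axis=0)
        return float(np.linalg.norm(span)) or 1.0


# ---------------------------------------------------------------------------
# pairwise segment predicates (vectorised over all edge pairs)
# ---------------------------------------------------------------------------

def _adjacency_matrix(es: Sequence[Edge]) -> np.ndarray:
    """Boolean matrix: True where two edges share an endpoint (or i == j)."""
    n = len(es)
    frm = np.array([e.from_idx for e in es])
    to = np.array([e.to_idx for e in es])
    adj = np.zeros((n, n), dtype=bool)
    for a, b in ((frm, frm), (frm, to), (to, frm), (to, to)):
        adj |= a[:, None] == b[None, :]
    adj |= np.eye(n, dtype=bool)
    return adj


def _pairwise_crossing_params(p0, p1, scale):
    """2D crossing parameters for every pair of segments.

    Returns (t, u, valid) of shape (n, n): segment i at parameter t and
    segment j at parameter u intersect when valid[i, j]; degenerate
    (near-parallel touching) pairs are reported via the second return.
    """
    d = (p1 - p0)[:, :2]
    o = p0[:, :2]
    # solve o_i + t d_i = o_j + u d_j
    denom = d[:, None, 0] * d[None, :, 1] - d[:, None, 1] * d[None, :, 0]
    dox = o[None, :, 0] - o[:, None, 0]
    doy = o[None, :, 1] - o[:, None, 1]
    eps = EPS_PRED * scale * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (dox * d[None, :, 1] - doy * d[None, :, 0]) / denom
        u = (dox * d[:, None, 1] - doy * d[:, None, 0]) / denom
    parallel = np.abs(denom) <= eps
    inside = (t > 0.0) & (t < 1.0) & (u > 0.0) & (u < 1.0)
    valid = inside & ~parallel
    return t, u, parallel


def _segment_distance_3d(p0, p1, q0, q1):
    """Min distance between 3D segment batches (broadcast over pairs)."""
    # Ericson, Real-Time Collision Detection, closest-point-of-segments
    d1 = p1 - p0
    d2 = q1 - q0
    r = p0[:, None, :] - q0[None, :, :]
    a = np.einsum("id,id->i", d1, d1)[:, None]
    e = np.einsum("jd,jd->j", d2, d2)[None, :]
    f = np.einsum("jd,ijd->ij", d2, r)
    c = np.einsum("id,ijd->ij", d1, r)
    b = np.einsum("id,jd->ij", d1, d2)
    denom = a * e - b * b
    tiny = 1e-300
    s = np.where(np.abs(denom) > tiny, (b * f - c * e) / np.where(denom == 0, 1, denom), 0.0)
    s = np.clip(s, 0.0, 1.0)
    t = np.where(e > tiny, (b * s + f) / np.where(e == 0, 1, e), 0.0)
    t_clamped = np.clip(t, 0.0, 1.0)
    # re-project s where t was clamped
    s = np.where(np.abs(t - t_clamped) > 0, np.clip((b * t_clamped - c) / np.where(a == 0, 1, a), 0.0, 1.0), s)
    t = t_clamped
    cp1 = p0[:, None, :] + s[..., None] * d1[:, None, :]
    cp2 = q0[None, :, :] + t[..., None] * d2[None, :, :]
    return np.linalg.norm(cp1 - cp2, axis=-1)


# ---------------------------------------------------------------------------
# construction and validation
# ---------------------------------------------------------------------------

def build_link(points, separators, closed_flags) -> PolygonalLink:
    """Validate and build a :class:`PolygonalLink`.

    Raises :class:`NonSimpleLinkError` when two non-adjacent edges
    intersect in 3D or an edge has (near) zero length, and
    :class:`ValueError` on malformed separators or undersized components.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    if not np.isfinite(pts).all():
        raise ValueError("points must be finite")
    seps = list(separators)
    if seps != sorted(set(seps)) or (seps and seps[0] != 0):
        raise ValueError("separators must be strictly increasing and start at 0")
    if len(closed_flags) != len(seps):
        raise ValueError("one closed flag per component required")
    link = PolygonalLink(pts, seps, list(closed_flags))
    for c in range(link.n_components):
        a, b = link.component_range(c)
        n = b - a
        if n < 2:
            raise ValueError(f"component {c} has fewer than 2 points")
        if link.closed_flags[c] and n < 3:
            raise ValueError(f"closed component {c} needs at least 3 points")
    scale = link.bbox_diag()
    p0, p1, comp, es = link.edge_arrays()
    lengths = np.linalg.norm(p1 - p0, axis=1)
    short = np.where(lengths <= EPS_PRED * scale)[0]
    if short.size:
        e = es[short[0]]
        raise NonSimpleLinkError(
            f"zero-length edge {e.edge_id} ({e.from_idx}->{e.to_idx})", (e.edge_id, e.edge_id)
        )
    check_simple(link)
    return link


def check_simple(link: PolygonalLink, tol: float | None = None) -> None:
    """Raise :class:`NonSimpleLinkError` if non-adjacent edges touch in 3D."""
    scale = link.bbox_diag()
    if tol is None:
        tol = EPS_PRED * scale * 100
    p0, p1, comp, es = link.edge_arrays()
    dist = _segment_distance_3d(p0, p1, p0, p1)
    adj = _adjacency_matrix(es)
    dist[adj] = np.inf
    i, j = np.unravel_index(np.argmin(dist), dist.shape)
    if dist[i, j] <= tol:
        raise NonSimpleLinkError(
            f"edges {es[i].edge_id} and {es[j].edge_id} intersect in 3D",
            (es[i].edge_id, es[j].edge_id),
        )


# ---------------------------------------------------------------------------
# projection regularity
# ---------------------------------------------------------------------------

def _regularity_report(link: PolygonalLink):
    """Return None when the standard projection is regular, else a reason."""
    scale = link.bbox_diag()
    tol = EPS_REGULAR * scale
    p0, p1, comp, es = link.edge_arrays()
    n = len(es)
    adj = _adjacency_matrix(es)
    t, u, parallel = _pairwise_crossing_params(p0, p1, scale)

    d2 = (p1 - p0)[:, :2]
    seglen = np.linalg.norm(d2, axis=1)
    # parallel overlap (projection): parallel pairs whose 2D distance ~ 0
    if parallel.any():
        q0, q1 = p0.copy(), p1.copy()
        q0[:, 2] = 0.0
        q1[:, 2] = 0.0
        dist2 = _segment_distance_3d(q0, q1, q0, q1)
        bad = parallel & ~adj & (dist2 < tol)
        # adjacent anti-parallel overlap also breaks the diagram
        shared_ok = np.zeros_like(bad)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            return f"edges {i} and {j} overlap in projection"
        # adjacent pairs: overlapping means doubling back
        badadj = parallel & adj & ~np.eye(n, dtype=bool)
        if badadj.any():
            for i, j in np.argwhere(badadj):
                if i >= j:
                    continue
                # same direction collinear continuation is fine; doubling back is not
                if np.dot(d2[i], d2[j]) < 0:
                    q0_, q1_ = p0[[i, j]].copy(), p1[[i, j]].copy()
                    q0_[:, 2] = 0
                    q1_[:, 2] = 0
                    dd = _segment_distance_3d(q0_[:1], q1_[:1], q0_[1:], q1_[1:])[0, 0]
                    if dd < tol:
                        # shares only an endpoint -> overlap beyond it?
                        li, lj = seglen[i], seglen[j]
                        if min(li, lj) > tol:
                            return f"adjacent edges {i} and {j} double back in projection"

    # vertex on a non-incident edge
    verts = link.points[:, :2]
    vt = verts[None, :, :] - p0[:, None, :2]  # (edges, verts, 2)
    denom = np.maximum(seglen, 1e-300)
    tpar = np.einsum("evd,ed->ev", vt, d2) / (denom ** 2)[:, None]
    tpar_c = np.clip(tpar, 0.0, 1.0)
    closest = p0[:, None, :2] + tpar_c[..., None] * d2[:, None, :]
    vdist = np.linalg.norm(verts[None, :, :] - closest, axis=-1)
    incident = np.zeros_like(vdist, dtype=bool)
    for k, e in enumerate(es):
        incident[k, e.from_idx] = True
        incident[k, e.to_idx] = True
    bad = (vdist < tol) & ~incident
    if bad.any():
        k, v = np.argwhere(bad)[0]
        return f"vertex {v} projects onto edge {k}"

    # crossings: collect, enforce separation from vertices and each other
    valid = (t > 0) & (t < 1) & (u > 0) & (u < 1) & ~parallel & ~adj
    iu = np.triu(valid, k=1)
    idx = np.argwhere(iu)
    if idx.size:
        ti = t[iu]
        # crossing too close to an edge endpoint
        margin = tol / np.maximum(seglen[idx[:, 0]], 1e-300)
        margin_u = tol / np.maximum(seglen[idx[:, 1]], 1e-300)
        ui = u[iu]
        if ((ti < margin) | (ti > 1 - margin) | (ui < margin_u) | (ui > 1 - margin_u)).any():
            return "crossing too close to a vertex"
        xy = p0[idx[:, 0], :2] + ti[:, None] * d2[idx[:, 0]]
        if len(xy) > 1:
            dd = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
            np.fill_diagonal(dd, np.inf)
            if dd.min() < tol:
                return "two crossings coincide (triple point)"
        # under/over must be resolved: z gap at the crossing
        dz = p1[:, 2] - p0[:, 2]
        z_i = p0[idx[:, 0], 2] + ti * dz[idx[:, 0]]
        z_j = p0[idx[:, 1], 2] + ui * dz[idx[:, 1]]
        if (np.abs(z_i - z_j) < tol).any():
            return "crossing with unresolved over/under (z coincidence)"
    return None


def is_regular(link: PolygonalLink) -> bool:
    return _regularity_report(link) is None


def ensure_general_position(link: PolygonalLink, seed: int) -> PolygonalLink:
    """Return ``link`` (unchanged) if its projection is regular, else a
    rigidly rotated copy with a regular projection.

    The rotations are drawn deterministically from ``seed``; failure after
    ``MAX_ROTATION_ATTEMPTS`` raises :class:`GeneralPositionError`.
    """
    if is_regular(link):
        return link
    rng = np.random.default_rng(seed)
    centroid = link.points.mean(axis=0)
    for _ in range(MAX_ROTATION_ATTEMPTS):
        rot = Rotation.random(random_state=rng)
        pts = (link.points - centroid) @ rot.as_matrix().T + centroid
        cand = PolygonalLink(pts, list(link.separators), list(link.closed_flags))
        if is_regular(cand):
            return cand
    raise GeneralPositionError(
        f"no regular projection found in {MAX_ROTATION_ATTEMPTS} rotations"
    )


# ---------------------------------------------------------------------------
# crossings
# ---------------------------------------------------------------------------

def rotate_link(link: PolygonalLink, seed: int) -> PolygonalLink:
    """Rigidly rotated copy (seeded random rotation about the centroid)."""
    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=rng).as_matrix()
    centroid = link.points.mean(axis=0)
    pts = (link.points - centroid) @ rot.T + centroid
    return PolygonalLink(pts, list(link.separators), list(link.closed_flags))


def crossing_sign(d_under: np.ndarray, d_over: np.ndarray) -> int:
    """Oriented sign: +1 when, travelling along the underpass, the overpass
    runs left to right."""
    cz = d_under[0] * d_over[1] - d_under[1] * d_over[0]
    return 1 if cz < 0 else -1


def find_crossings(link: PolygonalLink) -> list:
    """All crossings of the standard projection, as :class:`Crossing2D`.

    Requires a regular projection; raises
    :class:`NonRegularProjectionError` otherwise.
    """
    reason = _regularity_report(link)
    if reason is not None:
        raise NonRegularProjectionError(reason)
    p0, p1, comp, es = link.edge_arrays()
    adj = _adjacency_matrix(es)
    scale = link.bbox_diag()
    t, u, parallel = _pairwise_crossing_params(p0, p1, scale)
    valid = (t > 0) & (t < 1) & (u > 0) & (u < 1) & ~parallel & ~adj
    out = []
    d = p1 - p0
    for i, j in np.argwhere(np.triu(valid, k=1)):
        ti, uj = t[i, j], u[i, j]
        z_i = p0[i, 2] + ti * d[i, 2]
        z_j = p0[j, 2] + uj * d[j, 2]
        xy = tuple(p0[i, :2] + ti * d[i, :2])
        if z_i < z_j:
            und, ovr, tu, to = i, j, ti, uj
        else:
            und, ovr, tu, to = j, i, uj, ti
        sign = crossing_sign(d[und, :2], d[ovr, :2])
        out.append(
            Crossing2D(
                under_edge=int(und),
                over_edge=int(ovr),
                xy=xy,
                oriented_sign=sign,
                under_param=float(tu),
                over_param=float(to),
            )
        )
    return out


def writhe(link: PolygonalLink) -> int:
    return sum(c.oriented_sign for c in find_crossings(link))


def segment_hits(link: PolygonalLink, p_start, p_end, skip_edges=frozenset()):
    """Ordered projected crossings of an auxiliary 3D segment against the
    link's edges.

    Returns (ok, hits) with hits a list of (param_on_segment, edge_id,
    status) sorted along the segment; status is +1 when the segment
    passes over the edge.  ok is False when any interaction is degenerate
    (parallel overlap, touching a vertex, unresolved z, or two hits too
    close together); callers must then perturb or reject.
    """
    scale = link.bbox_diag()
    tol = EPS_REGULAR * scale
    p0s, p1s, comp, es = link.edge_arrays()
    d = p1s - p0s
    s0 = np.asarray(p_start, dtype=float)
    sd = np.asarray(p_end, dtype=float) - s0
    denom = sd[0] * d[:, 1] - sd[1] * d[:, 0]
    dox = p0s[:, 0] - s0[0]
    doy = p0s[:, 1] - s0[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (dox * d[:, 1] - doy * d[:, 0]) / denom  # param on segment
        u = (dox * sd[1] - doy * sd[0]) / denom  # param on edge
    seg_len = np.linalg.norm(sd[:2]) or 1e-300
    elens = np.maximum(np.linalg.norm(d[:, :2], axis=1), 1e-300)
    m_t = tol / seg_len
    m_u = tol / elens
    parallel = np.abs(denom) <= EPS_PRED * scale * scale
    hits = []
    for i in range(len(es)):
        if i in skip_edges:
            continue
        if parallel[i]:
            # overlap along the segment axis beyond a point contact?
            axis = sd[:2] / seg_len
            a0 = float((p0s[i][:2] - s0[:2]) @ axis)
            a1 = float((p1s[i][:2] - s0[:2]) @ axis)
            lo, hi = min(a0, a1), max(a0, a1)
            overlap = min(hi, seg_len) - max(lo, 0.0)
            lateral = abs(
                axis[0] * (p0s[i][1] - s0[1]) - axis[1] * (p0s[i][0] - s0[0])
            )
            if overlap > tol and lateral < tol:
                return False, []
            continue
        ti, ui = t[i], u[i]
        if ti <= 0 or ti >= 1 or ui <= 0 or ui >= 1:
            continue
        if ti < m_t or ti > 1 - m_t or ui < m_u[i] or ui > 1 - m_u[i]:
            return False, []
        z_seg = s0[2] + ti * sd[2]
        z_edge = p0s[i][2] + ui * d[i][2]
        if abs(z_seg - z_edge) < tol:
            return False, []
        hits.append((float(ti), i, 1 if z_seg > z_edge else -1))
    hits.sort()
    for (t1, _, _), (t2, _, _) in zip(hits, hits[1:]):
        if (t2 - t1) * seg_len < tol:
            return False, []
    return True, hits


def diagram_gauss_code(link: PolygonalLink) -> list:
    """Oriented Gauss code of the link's diagram: one pass sequence per
    component, entries (crossing_id, 'o'|'u', oriented_sign)."""
    crossings = find_crossings(link)
    es = link.edges()
    passes = {e.edge_id: [] for e in es}
    for cid, c in enumerate(crossings):
        passes[c.under_edge].append((c.under_param, cid, "u", c.oriented_sign))
        passes[c.over_edge].append((c.over_param, cid, "o", c.oriented_sign))
    comps = [[] for _ in range(link.n_components)]
    for e in es:
        for param, cid, ou, sign in sorted(passes[e.edge_id]):
            comps[e.component].append((cid, ou, sign))
    return comps


def mirror_link(link: PolygonalLink) -> PolygonalLink:
    """z-negated copy: every crossing swaps over/under and negates its sign."""
    pts = link.points.copy()
    pts[:, 2] = -pts[:, 2]
    return PolygonalLink(pts, list(link.separators), list(link.closed_flags))


def reverse_component(link: PolygonalLink, c: int) -> PolygonalLink:
    """Copy of ``link`` with the orientation of component ``c`` reversed."""
    pts = link.points.copy()
    a, b = link.component_range(c)
    pts[a:b] = pts[a:b][::-1]
    return PolygonalLink(pts, list(link.separators), list(link.closed_flags))


def intersection_matrix(link: PolygonalLink, edge_set_E=None, edge_set_F=None) -> np.ndarray:
    """Signed over/under matrix: entry(i, j) = +1 iff edge i crosses over
    edge j in projection, -1 iff under, 0 otherwise.

    With ``edge_set_E == edge_set_F`` (default: all edges) the matrix is
    antisymmetric with zero diagonal.
    """
    crossings = find_crossings(link)
    n_edges = len(link.edges())
    full = np.zeros((n_edges, n_edges), dtype=int)
    for c in crossings:
        full[c.over_edge, c.under_edge] = 1
        full[c.under_edge, c.over_edge] = -1
    if edge_set_E is None and edge_set_F is None:
        return full
    E = list(edge_set_E) if edge_set_E is not None else list(range(n_edges))
    F = list(edge_set_F) if edge_set_F is not None else list(range(n_edges))
    return full[np.ix_(E, F)]


# ---------------------------------------------------------------------------
# coordinate file round trip
# ---------------------------------------------------------------------------

def dumps_coords(link: PolygonalLink) -> str:
    """Plain-text serialisation: '# closed'/'# open' header then one
    'x y z' line per point; blank line between components."""
    blocks = []
    for c in range(link.n_components):
        head = "# closed" if link.closed_flags[c] else "# open"
        rows = [head]
        for p in link.component_points(c):
            rows.append(" ".join(f"{v:.12g}" for v in p))
        blocks.append("\n".join(rows))
    return "\n\n".join(blocks) + "\n"


def loads_coords(text: str) -> PolygonalLink:
    points = []
    separators = []
    closed_flags = []
    current = []
    closed = None

    def flush():
        nonlocal current, closed
        if current:
            separators.append(len(points))
            points.extend(current)
            closed_flags.append(bool(closed))
        current = []
        closed = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            flush()
            continue
        if line.startswith("#"):
            tag = line[1:].strip().lower()
            if tag not in ("closed", "open"):
                raise ValueError(f"line {lineno}: unknown component header {line!r}")
            flush()
            closed = tag == "closed"
            continue
        vals = line.split()
        if len(vals) != 3:
            raise ValueError(f"line {lineno}: expected 'x y z', got {line!r}")
        try:
            current.append([float(v) for v in vals])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: bad number in {line!r}") from exc
        if closed is None:
            closed = False
    flush()
    if not points:
        raise ValueError("no coordinates found")
    return build_link(np.array(points), separators, closed_flags)


def write_coords(link: PolygonalLink, path) -> None:
    with open(path, "w") as fh:
        fh.write(dumps_coords(link))


def read_coords(path) -> PolygonalLink:
    with open(path) as fh:
        return loads_coords(fh.read())
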