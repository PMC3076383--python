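"""Minimal Structure Reduction: iterated generalized chain moves that
replace a subpath with the segment joining its endpoints whenever doing
so provably preserves the ambient isotopy class.

A move candidate is admissible when
  C1  the subpath M is ascending or descending: at every self-crossing
      of M the first-met strand status is consistent;
  C2  the over/under statuses of M against other components form a set
      with at most one element;
  C3  the union of C2's set with the statuses of M against the rest of
      its own component has at most one element;
and additionally the replacement segment's own crossing statuses agree
with that single status (so M and its replacement can both be lifted to
the same side of everything else), the replacement keeps the link simple
in 3D, and its projection stays regular.  The intersection matrix is
maintained incrementally: rows/columns of removed edges are deleted and
a single freshly computed row/column is inserted for the new edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .linkcore import (
    PolygonalLink,
    ensure_general_position,
    intersection_matrix,
    EPS_PRED,
    EPS_REGULAR,
)

__all__ = [
    "MoveCandidate",
    "ReductionTrace",
    "grm_conditions",
    "grm",
    "msr_reduce",
    "move_stats",
    "trace_to_tsv",
]


@dataclass(frozen=True)
class MoveCandidate:
    component: int
    i_s: int  # global point index of the subpath start
    i_f: int  # global point index of the subpath end (may wrap on closed comps)
    span: int  # number of edges replaced (>= 2)

    @property
    def move_length(self) -> int:
        """span - 2: the classical one-vertex elementary move has length 0."""
        return self.span - 2


@dataclass
class ReductionTrace:
    steps: list = field(default_factory=list)  # (residual, length, comp, i_s, i_f)
    partial: bool = False

    def move_lengths(self):
        return [s[1] for s in self.steps]


# ---------------------------------------------------------------------------
# candidate bookkeeping
# ---------------------------------------------------------------------------

def _component_edge_ids(link, c):
    """Global edge ids of component c, in traversal order."""
    eid = 0
    out = None
    for ci in range(link.n_components):
        a, b = link.component_range(ci)
        n_edges = (b - a - 1) + (1 if link.closed_flags[ci] else 0)
        if ci == c:
            out = list(range(eid, eid + n_edges))
        eid += n_edges
    return out


def _subpath_edges(link, cand: MoveCandidate):
    """Edge ids of the subpath, in traversal order."""
    a, b = link.component_range(cand.component)
    k = b - a
    comp_edges = _component_edge_ids(link, cand.component)
    j0 = cand.i_s - a
    if link.closed_flags[cand.component]:
        return [comp_edges[(j0 + r) % k] for r in range(cand.span)]
    return comp_edges[j0: j0 + cand.span]


def grm_conditions(link: PolygonalLink, matrix: np.ndarray, cand: MoveCandidate):
    """Evaluate the admissibility conditions on the subpath.

    Returns (ok, which_failed) with which_failed in {'C1','C2','C3',None}.
    """
    m_edges = _subpath_edges(link, cand)
    m_set = set(m_edges)
    # C1: self-crossings of M, first-met status
    sub = matrix[np.ix_(m_edges, m_edges)]
    s1 = set(sub[np.triu_indices(len(m_edges), k=1)]) - {0}
    if len(s1) > 1:
        return False, "C1"
    comp_edges = set(_component_edge_ids(link, cand.component))
    own_rest = sorted(comp_edges - m_set)
    others = sorted(set(range(matrix.shape[0])) - comp_edges)
    s2 = set(matrix[np.ix_(m_edges, others)].ravel()) - {0} if others else set()
    if len(s2) > 1:
        return False, "C2"
    s_own = set(matrix[np.ix_(m_edges, own_rest)].ravel()) - {0} if own_rest else set()
    if len(s2 | s_own) > 1:
        return False, "C3"
    return True, None


def _segment_statuses(link, p_start, p_end, skip_edges):
    """Over/under statuses of segment (p_start -> p_end) against the link's
    edges (projection), excluding ids in ``skip_edges``; see
    :func:`skeinpath.linkcore.segment_hits`."""
    from .linkcore import segment_hits

    ok, hits = segment_hits(link, p_start, p_end, skip_edges)
    return ok, {e: st for _, e, st in hits}


def _vertices_clear_of_segment(link, p_start, p_end, skip_points):
    """No link vertex (other than the segment's endpoints) may project
    onto the new segment."""
    scale = link.bbox_diag()
    tol = EPS_REGULAR * scale
    v = link.points[:, :2]
    s0 = np.asarray(p_start)[:2]
    sd = np.asarray(p_end)[:2] - s0
    L2 = float(sd @ sd) or 1e-300
    tpar = np.clip(((v - s0) @ sd) / L2, 0.0, 1.0)
    dist = np.linalg.norm(v - (s0 + tpar[:, None] * sd), axis=1)
    mask = np.ones(len(v), dtype=bool)
    for idx in skip_points:
        mask[idx] = False
    return not (dist[mask] < tol).any()


def _contract(link, cand: MoveCandidate):
    """Apply the contraction; returns (link', surviving old edge ids in
    new traversal order with None at the new edge, new index of i_s)."""
    a, b = link.component_range(cand.component)
    k = b - a
    closed = link.closed_flags[cand.component]
    j_s = cand.i_s - a
    removed_local = set()
    for r in range(1, cand.span):
        removed_local.add((j_s + r) % k if closed else j_s + r)
    if closed:
        # rebase the cycle at i_f so the kept arc is contiguous
        j_f = (j_s + cand.span) % k
        order = [j for j in [(j_f + r) % k for r in range(k)] if j not in removed_local]
    else:
        order = [j for j in range(k) if j not in removed_local]
    keep_global = [a + j for j in order]

    new_points = np.vstack(
        [link.points[: a], link.points[keep_global], link.points[b:]]
    )
    shift = len(removed_local)
    new_seps = [s if s <= a else s - shift for s in link.separators]
    new_link = PolygonalLink(new_points, new_seps, list(link.closed_flags))

    # map new edges -> old edge ids (None for the freshly created edge)
    old_es = link.edges()
    old_pair_to_id = {(e.from_idx, e.to_idx): e.edge_id for e in old_es}
    global_new_old = []
    new_es = new_link.edges()
    # build new->old point index map
    new_to_old = {}
    pos = 0
    for i in range(a):
        new_to_old[pos] = i
        pos += 1
    for g in keep_global:
        new_to_old[pos] = g
        pos += 1
    for i in range(b, link.n_points):
        new_to_old[pos] = i
        pos += 1
    for e in new_es:
        key = (new_to_old[e.from_idx], new_to_old[e.to_idx])
        global_new_old.append(old_pair_to_id.get(key))
    return new_link, global_new_old, new_to_old


def grm(link: PolygonalLink, matrix: np.ndarray, start_index: int):
    """Try move candidates starting at point ``start_index``, longest
    first; commit the first admissible one.

    Returns (link', matrix', accepted, move).  The returned matrix is the
    incremental update (never a full recomputation).
    """
    if matrix.shape[0] != len(link.edges()):
        raise RuntimeError("intersection matrix inconsistent with link")
    c = link.component_of_point(start_index)
    a, b = link.component_range(c)
    k = b - a
    closed = link.closed_flags[c]
    if closed:
        spans = range(min(k - 2, k - 1), 1, -1)
    else:
        spans = range(b - 1 - start_index, 1, -1)
    for span in spans:
        if closed:
            i_f = a + ((start_index - a + span) % k)
        else:
            i_f = start_index + span
        cand = MoveCandidate(c, start_index, i_f, span)
        ok, _ = grm_conditions(link, matrix, cand)
        if not ok:
            continue
        result = _try_commit(link, matrix, cand)
        if result is not None:
            link2, matrix2 = result
            return link2, matrix2, True, cand
    return link, matrix, False, None


def _try_commit(link, matrix, cand):
    m_edges = _subpath_edges(link, cand)
    m_set = set(m_edges)
    # status set of M against everything outside M
    rest = [e for e in range(matrix.shape[0]) if e not in m_set]
    s3 = set(matrix[np.ix_(m_edges, rest)].ravel()) - {0} if rest else set()

    p_s = link.points[cand.i_s]
    p_f = link.points[cand.i_f]
    seg = p_f - p_s
    if np.linalg.norm(seg) <= EPS_PRED * link.bbox_diag():
        return None

    # projection statuses of the replacement segment vs the remainder
    ok, seg_statuses = _segment_statuses(link, p_s, p_f, skip_edges=m_set)
    if not ok:
        return None
    # drop statuses against edges that will vanish with M (none: skipped)
    if len(s3 | set(seg_statuses.values())) > 1:
        return None
    removed_pts = set()
    a, b = link.component_range(cand.component)
    k = b - a
    j_s = cand.i_s - a
    for r in range(1, cand.span):
        removed_pts.add(a + ((j_s + r) % k) if link.closed_flags[cand.component] else cand.i_s + r)
    if not _vertices_clear_of_segment(
        link, p_s, p_f, removed_pts | {cand.i_s, cand.i_f}
    ):
        return None

    # 3D simplicity of the new edge against all remaining edges
    from .linkcore import _segment_distance_3d

    p0s, p1s, comp, es = link.edge_arrays()
    keep = [e.edge_id for e in es if e.edge_id not in m_set]
    adjacent = {
        e.edge_id
        for e in es
        if e.edge_id in keep and {e.from_idx, e.to_idx} & {cand.i_s, cand.i_f}
    }
    check = [e for e in keep if e not in adjacent]
    if check:
        dd = _segment_distance_3d(p_s[None, :], p_f[None, :], p0s[check], p1s[check])
        if dd.min() <= EPS_PRED * link.bbox_diag() * 100:
            return None

    new_link, new_old, new_to_old = _contract(link, cand)
    # incremental matrix: slice surviving rows/cols, insert the new edge
    n_new = len(new_old)
    new_matrix = np.zeros((n_new, n_new), dtype=matrix.dtype)
    old_ids = [o for o in new_old if o is not None]
    sel = [i for i, o in enumerate(new_old) if o is not None]
    new_matrix[np.ix_(sel, sel)] = matrix[np.ix_(old_ids, old_ids)]
    new_eid = new_old.index(None)
    for i, o in enumerate(new_old):
        if o is None:
            continue
        st = seg_statuses.get(o, 0)
        new_matrix[new_eid, i] = st
        new_matrix[i, new_eid] = -st
    return new_link, new_matrix


def msr_reduce(link: PolygonalLink, iteration_limit: int | None = None, seed: int = 0):
    """Reduce until no move is admissible (minimal structure) or the
    sweep limit is reached.  Returns (reduced link, ReductionTrace)."""
    from .linkcore import is_regular

    trace = ReductionTrace()
    link = ensure_general_position(link, seed)
    if iteration_limit is None:
        iteration_limit = 10 * link.n_points
    if iteration_limit == 0:
        return link, trace
    sweeps = 0
    for _round in range(4):
        matrix = intersection_matrix(link)
        while True:
            accepted_any = False
            start = 0
            while start < link.n_points:
                link2, matrix2, accepted, move = grm(link, matrix, start)
                if accepted:
                    link, matrix = link2, matrix2
                    trace.steps.append(
                        (link.n_points, move.move_length, move.component, move.i_s, move.i_f)
                    )
                    accepted_any = True
                    start = min(start, link.n_points - 1)
                else:
                    start += 1
            sweeps += 1
            if sweeps >= iteration_limit and accepted_any:
                trace.partial = True
                return link, trace
            if not accepted_any:
                break
        # a committed move can drop a fresh crossing near an existing one;
        # re-rotate into general position and keep reducing
        if is_regular(link):
            return link, trace
        link = ensure_general_position(link, seed + 7919 * (_round + 1))
    return link, trace


def move_stats(traces) -> dict:
    """Descriptive statistics over reduction traces."""
    traces = list(traces)
    if not traces:
        raise ValueError("need at least one trace")
    lengths = [l for tr in traces for l in tr.move_lengths()]
    pairs = [(s[0], s[1]) for tr in traces for s in tr.steps]
    if not lengths:
        return {
            "n_moves": 0,
            "quartiles": (None, None, None),
            "mean": None,
            "zero_fraction": None,
            "pairs": [],
        }
    arr = np.array(lengths, dtype=float)
    q1, q2, q3 = np.percentile(arr, [25, 50, 75])
    return {
        "n_moves": len(lengths),
        "quartiles": (float(q1), float(q2), float(q3)),
        "mean": float(arr.mean()),
        "zero_fraction": float((arr == 0).mean()),
        "pairs": pairs,
    }


def trace_to_tsv(trace: ReductionTrace) -> str:
    rows = ["step\tresidual_points\tmove_length\tcomponent\ti_s\ti_f"]
    for i, (res, length, comp, i_s, i_f) in enumerate(trace.steps):
        rows.append(f"{i}\t{res}\t{length}\t{comp}\t{i_s}\t{i_f}")
    return "\n".join(rows) + "\n"
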