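"""Protein backbone ingestion: Calpha extraction from PDB text, gap
splitting (gaps are chain terminators, never bridged by straight lines),
closure, classification and knotted-core trimming.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .linkcore import (
    PolygonalLink,
    build_link,
    NonSimpleLinkError,
)
from .msr import msr_reduce
from .homfly import homfly as _homfly, identify_knot, ONE, LaurentPoly2

logger = logging.getLogger(__name__)

__all__ = [
    "BackboneChain",
    "Part",
    "CoreResult",
    "PdbParseError",
    "read_backbone",
    "split_parts",
    "close_and_classify",
    "knotted_core",
    "format_pdb",
    "GAP_THRESHOLD_A",
]

GAP_THRESHOLD_A = 4.5
MIN_PART_RESIDUES = 4


class PdbParseError(ValueError):
    def __init__(self, msg, lineno=None):
        super().__init__(msg)
        self.lineno = lineno


@dataclass
class BackboneChain:
    pdb_id: str
    chain_id: str
    residues: list  # ordered (residue number, xyz ndarray)

    @property
    def n_residues(self):
        return len(self.residues)

    def coords(self):
        return np.array([xyz for _, xyz in self.residues])


@dataclass
class Part:
    chain: BackboneChain
    start: int  # residue index range within the chain, half-open
    stop: int
    link: PolygonalLink  # open, single component

    @property
    def n_residues(self):
        return self.stop - self.start

    def residue_numbers(self):
        return (self.chain.residues[self.start][0], self.chain.residues[self.stop - 1][0])


@dataclass
class CoreResult:
    n_trim: int
    c_trim: int
    knot: object  # KnotRecord of the untrimmed part


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def read_backbone(pdb_text: str, chain_filter=None) -> list:
    """Calpha trace per chain from PDB-format text.

    Model 1 only; altloc 'A' or blank; HETATM excluded; one Calpha per
    residue (first kept); chains with fewer than 4 residues are skipped
    with a logged reason.  Unparseable ATOM records raise
    :class:`PdbParseError` naming the line.
    """
    pdb_id = ""
    chains: dict = {}
    order: list = []
    model = 0
    in_later_model = False
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6]
        if rec.startswith("HEADER"):
            pdb_id = line[62:66].strip()
        elif rec.startswith("MODEL"):
            model += 1
            in_later_model = model > 1
        elif rec.startswith("ENDMDL"):
            pass
        elif rec == "ATOM  ":
            if in_later_model:
                continue
            if len(line) < 54:
                raise PdbParseError(f"line {lineno}: truncated ATOM record", lineno)
            name = line[12:16].strip()
            if name != "CA":
                continue
            altloc = line[16]
            if altloc not in (" ", "A"):
                continue
            chain_id = line[21]
            if chain_filter is not None and chain_id not in chain_filter:
                continue
            try:
                resnum = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise PdbParseError(
                    f"line {lineno}: unparseable ATOM record: {line!r}", lineno
                ) from exc
            icode = line[26]
            key = chain_id
            if key not in chains:
                chains[key] = {"residues": [], "seen": set()}
                order.append(key)
            if (resnum, icode) in chains[key]["seen"]:
                continue  # first altloc/duplicate kept
            chains[key]["seen"].add((resnum, icode))
            chains[key]["residues"].append((resnum, np.array([x, y, z])))
    out = []
    for cid in order:
        residues = chains[cid]["residues"]
        if len(residues) < MIN_PART_RESIDUES:
            logger.info("chain %s skipped: only %d Calpha atoms", cid, len(residues))
            continue
        out.append(BackboneChain(pdb_id=pdb_id, chain_id=cid, residues=residues))
    return out


def format_pdb(coords, chain_id="A", pdb_id="XXXX", start_resnum=1) -> str:
    """Minimal single-chain PDB text for the given Calpha coordinates
    (test/fixture utility)."""
    lines = [f"HEADER    SYNTHETIC                               01-JAN-00   {pdb_id:<4s}"]
    serial = 1
    for i, (x, y, z) in enumerate(np.asarray(coords, dtype=float)):
        lines.append(
            f"ATOM  {serial:5d}  CA  ALA {chain_id}{start_resnum + i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
        serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# parts
# ---------------------------------------------------------------------------

def split_parts(chain: BackboneChain, gap_threshold_A: float = GAP_THRESHOLD_A) -> list:
    """Split at every consecutive Calpha distance above the threshold
    (gaps terminate the chain); parts shorter than 4 residues are
    dropped."""
    coords = chain.coords()
    d = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    cuts = [0] + [i + 1 for i in np.where(d > gap_threshold_A)[0]] + [len(coords)]
    parts = []
    for a, b in zip(cuts, cuts[1:]):
        if b - a < MIN_PART_RESIDUES:
            logger.info(
                "part %s[%d:%d] dropped: only %d residues", chain.chain_id, a, b, b - a
            )
            continue
        link = build_link(coords[a:b], [0], [False])
        parts.append(Part(chain=chain, start=a, stop=b, link=link))
    return parts


# ---------------------------------------------------------------------------
# closure and classification
# ---------------------------------------------------------------------------

def _close_link(link: PolygonalLink, closure: str, seed: int) -> PolygonalLink:
    """Close an open single-component link.

    direct: mark closed (the closing edge joins the termini straight);
    radial: extend both termini outward from the centroid to a bounding
    sphere and close through a point far outside it.
    """
    pts = link.points
    rng = np.random.default_rng(seed)
    for attempt in range(10):
        if closure == "direct":
            cand_pts = pts
        elif closure == "radial":
            centroid = pts.mean(axis=0)
            radius = 2.0 * np.linalg.norm(pts - centroid, axis=1).max() + 1.0
            ends = []
            for p in (pts[-1], pts[0]):
                v = p - centroid
                n = np.linalg.norm(v)
                if n < 1e-9:
                    v = rng.normal(size=3)
                    n = np.linalg.norm(v)
                ends.append(centroid + v / n * radius)
            far_dir = ends[0] - centroid + ends[1] - centroid
            if np.linalg.norm(far_dir) < 1e-9 * radius:
                far_dir = np.cross(ends[0] - centroid, rng.normal(size=3))
            far = centroid + far_dir / np.linalg.norm(far_dir) * 3.0 * radius
            cand_pts = np.vstack([pts, ends[0], far, ends[1]])
        else:
            raise ValueError(f"unknown closure policy {closure!r}")
        try:
            return build_link(cand_pts, [0], [True])
        except NonSimpleLinkError:
            # closing segment hits the structure: jitter termini
            jitter = rng.normal(scale=1e-3 * link.bbox_diag(), size=(2, 3))
            pts = pts.copy()
            pts[0] = pts[0] + jitter[0]
            pts[-1] = pts[-1] + jitter[1]
    raise NonSimpleLinkError("closure failed after 10 jitter attempts")


def close_and_classify(part, closure: str = "direct", seed: int = 0, strategy: str = "greedy"):
    """MSR-reduce the open chain, close it, re-reduce and classify.

    Accepts a :class:`Part` or a bare open PolygonalLink.  Returns
    (KnotRecord or 'unidentified', polynomial).
    """
    if closure not in ("direct", "radial"):
        raise ValueError(f"unknown closure policy {closure!r}")
    link = part.link if isinstance(part, Part) else part
    reduced, _ = msr_reduce(link, seed=seed)
    if reduced.n_points < 3:
        return identify_knot(ONE), ONE
    closed = _close_link(reduced, closure, seed)
    poly = _homfly(closed, strategy=strategy, seed=seed)
    return identify_knot(poly), poly


def _is_unknot(poly: LaurentPoly2) -> bool:
    return poly == ONE


def knotted_core(part, closure: str = "direct", seed: int = 0, strategy: str = "greedy") -> CoreResult:
    """Minimal terminal trims that unknot the part.

    Scans the N-terminus first (n_trim = minimal N-deletion that
    unknots, C intact), then the C-terminus with the N-trim held at the
    last still-knotted value (n_trim - 1).
    """
    link = part.link if isinstance(part, Part) else part
    coords = link.points
    rec, poly = close_and_classify(link, closure, seed, strategy)
    if _is_unknot(poly):
        raise ValueError("nothing to core: part is not knotted")

    def classify_trimmed(n, c):
        sub = coords[n: len(coords) - c]
        if len(sub) < MIN_PART_RESIDUES:
            return True  # trivially unknotted
        sublink = build_link(sub, [0], [False])
        _, p = close_and_classify(sublink, closure, seed, strategy)
        return _is_unknot(p)

    n_trim = None
    for k in range(1, len(coords) - MIN_PART_RESIDUES + 1):
        if classify_trimmed(k, 0):
            n_trim = k
            break
    if n_trim is None:
        n_trim = len(coords) - MIN_PART_RESIDUES
    c_trim = None
    base_n = n_trim - 1
    for j in range(1, len(coords) - base_n - MIN_PART_RESIDUES + 1):
        if classify_trimmed(base_n, j):
            c_trim = j
            break
    if c_trim is None:
        c_trim = len(coords) - base_n - MIN_PART_RESIDUES
    return CoreResult(n_trim=n_trim, c_trim=c_trim, knot=rec)
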