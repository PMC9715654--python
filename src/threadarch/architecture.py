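"""Architectural feature detection on filament coordinate models.

Given any coordinate model of a filament this module establishes the
subunit ordering along the helical axis (the n, n±1, n±2 labelling), and
then detects and quantifies:

* donor strand complementation — the N-terminal tail of subunit n buried
  in the preceding subunits, read out as tail heavy-atom contact fractions
  binned by acceptor offset;
* intermolecular isopeptide bonds — short, planar contacts between a
  side-chain amide/carboxylate carbon and an α-amino or lysine side-chain
  nitrogen of another subunit (in the thread: Asn57 of subunit n to the
  α-amino group of Asp24 of subunit n+2);
* N-glycosylation sequons (N-x≠P-S/T) in a sequence, and the glycan trees
  actually modelled on the structure (core = two GlcNAc in series, complete
  when the hexasaccharide 2 GlcNAc + 2 Man + 1 Glc + 1 6-sulfoquinovose is
  present);
* the filament diameter, as twice the 99th-percentile radial atom distance
  from the axis (robust to single outlier atoms).

Filament polarity is not assumed: subunit offsets are reported as signed
index differences relative to the axial ordering, never as a direction
toward or away from the cell.
"""

from __future__ import annotations

import re
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .io import Chain, StructureModel, logger

# ---------------------------------------------------------------------------
# Subunit indexing


@dataclass
class SubunitIndexing:
    """chain_id → subunit index n, ascending along the helical axis."""

    index: dict[str, int]
    axis_point: np.ndarray
    axis_dir: np.ndarray

    def offset(self, donor_chain: str, acceptor_chain: str) -> int:
        return self.index[acceptor_chain] - self.index[donor_chain]


def index_subunits(model: StructureModel, tie_tol: float = 0.5) -> SubunitIndexing:
    """Order chains by centroid projection onto the estimated helical axis."""
    from .helix import axis_from_centroids

    if len(model.chains) < 2:
        raise ValueError("subunit indexing needs at least 2 chains")
    axis_point, axis_dir = axis_from_centroids(model)
    proj = {
        c.chain_id: float((c.coords(hetero=False).mean(axis=0) - axis_point) @ axis_dir)
        for c in model.chains
    }
    ordered = sorted(proj, key=lambda cid: (proj[cid], cid))
    for a, b in zip(ordered, ordered[1:]):
        if abs(proj[a] - proj[b]) < tie_tol:
            logger.warning(
                "chains %s and %s have overlapping axial projections (Δ=%.2f Å); "
                "ties broken by chain id", a, b, proj[b] - proj[a],
            )
    return SubunitIndexing({cid: i for i, cid in enumerate(ordered)}, axis_point, axis_dir)


# ---------------------------------------------------------------------------
# Donor strand complementation


@dataclass
class DscChainReport:
    chain_id: str
    tail_range: tuple[int, int]  # seq_positions, inclusive
    fractions: dict[int, float]  # acceptor offset k -> share of tail contacts
    called: list[int]  # offsets with fraction >= threshold
    beta_pairs: dict[int, int]  # offset -> backbone N-O pairs <= hbond cutoff


@dataclass
class DscReport:
    per_chain: list[DscChainReport]

    def called_offsets(self) -> list[int]:
        """Offsets called in at least half of the reporting chains."""
        if not self.per_chain:
            return []
        counts: dict[int, int] = {}
        for rep in self.per_chain:
            for k in rep.called:
                counts[k] = counts.get(k, 0) + 1
        return sorted(k for k, c in counts.items() if c >= len(self.per_chain) / 2)


def detect_dsc(
    model: StructureModel,
    indexing: SubunitIndexing | None = None,
    tail_length: int = 10,
    contact_cutoff: float = 4.5,
    min_fraction: float = 0.2,
    hbond_cutoff: float = 3.5,
) -> DscReport:
    """Bin each chain's tail heavy-atom contacts by acceptor subunit offset.

    The tail is the first ``tail_length`` polymer residues (the exact tail
    boundary is not knowable from the map; it is a free parameter).  A DSC
    call is made for offset k (acceptor = subunit n−k) when at least
    ``min_fraction`` of all inter-chain tail contacts land in that chain.
    β-pairing evidence counts backbone N–O pairs within the hydrogen-bond
    proxy cutoff.
    """
    indexing = indexing or index_subunits(model)
    chain_of_point: list[str] = []
    pts = []
    for chain in model.chains:
        for res in chain.residues:
            for atom in res.atoms:
                if atom.element != "H":
                    pts.append(atom.xyz)
                    chain_of_point.append(chain.chain_id)
    pts = np.array(pts)
    tree = cKDTree(pts)
    chain_ids = np.array(chain_of_point)

    reports = []
    for chain in model.chains:
        polymer = chain.polymer()
        if len(polymer) < tail_length:
            logger.warning("chain %s shorter than tail_length=%d; skipped", chain.chain_id, tail_length)
            continue
        tail = polymer[:tail_length]
        tail_pts = np.array([a.xyz for r in tail for a in r.atoms if a.element != "H"])
        counts: dict[int, int] = {}
        for neighbours in tree.query_ball_point(tail_pts, contact_cutoff):
            for idx in neighbours:
                other = chain_ids[idx]
                if other == chain.chain_id:
                    continue
                k = indexing.index[chain.chain_id] - indexing.index[str(other)]
                counts[k] = counts.get(k, 0) + 1
        total = sum(counts.values())
        fractions = {k: c / total for k, c in sorted(counts.items())} if total else {}
        called = sorted(k for k, f in fractions.items() if f >= min_fraction and k > 0)
        beta = {}
        tail_n = np.array([a.xyz for r in tail for a in r.atoms if a.name == "N"]).reshape(-1, 3)
        tail_o = np.array([a.xyz for r in tail for a in r.atoms if a.name == "O"]).reshape(-1, 3)
        for k in called:
            acc_index = indexing.index[chain.chain_id] - k
            acc_chain = next(c for c in model.chains if indexing.index[c.chain_id] == acc_index)
            acc_n = np.array([a.xyz for r in acc_chain.polymer() for a in r.atoms if a.name == "N"]).reshape(-1, 3)
            acc_o = np.array([a.xyz for r in acc_chain.polymer() for a in r.atoms if a.name == "O"]).reshape(-1, 3)
            n_pairs = 0
            if len(tail_n) and len(acc_o):
                n_pairs += int((cKDTree(acc_o).query(tail_n)[0] <= hbond_cutoff).sum())
            if len(tail_o) and len(acc_n):
                n_pairs += int((cKDTree(acc_n).query(tail_o)[0] <= hbond_cutoff).sum())
            beta[k] = n_pairs
        reports.append(
            DscChainReport(
                chain.chain_id,
                (tail[0].seq_position, tail[-1].seq_position),
                fractions,
                called,
                beta,
            )
        )
    return DscReport(reports)


# ---------------------------------------------------------------------------
# Isopeptide bonds

#: side-chain amide/carboxylate carbon per donor residue type
_DONOR_ATOMS = {"ASN": "CG", "ASP": "CG", "GLN": "CD", "GLU": "CD"}
#: the side-chain atom preceding the donor carbon (for the planarity dihedral)
_DONOR_PREV = {"ASN": "CB", "ASP": "CB", "GLN": "CG", "GLU": "CG"}


@dataclass
class BondCandidate:
    donor_chain: str
    donor_position: int
    donor_residue: str
    donor_atom: str
    acceptor_chain: str
    acceptor_position: int
    acceptor_atom: str
    distance: float
    planarity_deviation: float | None  # degrees; None when not computable
    offset: int  # acceptor subunit index − donor subunit index


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = v @ w
    y = np.cross(b1, v) @ w
    return float(np.degrees(np.arctan2(y, x)))


def detect_isopeptide(
    model: StructureModel,
    indexing: SubunitIndexing | None = None,
    bond_cutoff: float = 1.8,
    planarity_max: float = 30.0,
    survey: bool = False,
) -> list[BondCandidate]:
    """Find intermolecular isopeptide bond candidates by geometry.

    Donors are the side-chain amide/carboxylate carbons of Asn/Asp/Gln/Glu
    (falling back to a coarse model's single SC pseudo-atom); acceptors are
    the α-amino nitrogen of each chain's first modelled residue plus every
    lysine NZ.  A candidate needs donor–acceptor distance within the bond
    cutoff (2.5 Å in survey mode, for unrefined models) and, when the
    flanking atoms exist, an amide-plane dihedral within ``planarity_max``
    of planarity.
    """
    indexing = indexing or index_subunits(model)
    cutoff = 2.5 if survey else bond_cutoff

    donors = []  # (chain_id, res, donor_atom, prev_atom)
    for chain in model.chains:
        for res in chain.polymer():
            if res.name not in _DONOR_ATOMS:
                continue
            atom = res.atom(_DONOR_ATOMS[res.name]) or res.atom("SC")
            if atom is None:
                continue
            prev = res.atom(_DONOR_PREV[res.name]) or res.atom("CA")
            donors.append((chain.chain_id, res, atom, prev))

    acceptors = []  # (chain_id, res, n_atom, next_atom)
    for chain in model.chains:
        polymer = chain.polymer()
        if polymer:
            first = polymer[0]
            n_atom = first.atom("N")
            if n_atom is not None:
                acceptors.append((chain.chain_id, first, n_atom, first.atom("CA")))
        for res in polymer:
            if res.name == "LYS":
                nz = res.atom("NZ")
                if nz is not None:
                    acceptors.append((chain.chain_id, res, nz, res.atom("CE")))

    candidates = []
    for d_chain, d_res, d_atom, d_prev in donors:
        for a_chain, a_res, a_atom, a_next in acceptors:
            if d_chain == a_chain:
                continue
            dist = float(np.linalg.norm(d_atom.xyz - a_atom.xyz))
            if dist > cutoff:
                continue
            deviation = None
            if d_prev is not None and a_next is not None:
                dih = _dihedral(d_prev.xyz, d_atom.xyz, a_atom.xyz, a_next.xyz)
                deviation = min(abs(dih), abs(180.0 - abs(dih)))
                if deviation > planarity_max:
                    continue
            candidates.append(
                BondCandidate(
                    donor_chain=d_chain,
                    donor_position=d_res.seq_position,
                    donor_residue=d_res.name,
                    donor_atom=d_atom.name,
                    acceptor_chain=a_chain,
                    acceptor_position=a_res.seq_position,
                    acceptor_atom=a_atom.name,
                    distance=dist,
                    planarity_deviation=deviation,
                    offset=indexing.offset(d_chain, a_chain),
                )
            )
    candidates.sort(key=lambda c: (c.donor_chain, c.donor_position, c.acceptor_chain))
    return candidates


# ---------------------------------------------------------------------------
# Sequons


@dataclass
class SequonHit:
    position: int  # numbering of the N, respecting the supplied offset
    triplet: str
    source: str  # "sequence" or "model"


_SEQUON_RE = re.compile(r"(?=(N[^P][ST]))")


def scan_sequons(sequence: str, numbering_start: int = 1, source: str = "sequence") -> list[SequonHit]:
    """All N-x(≠P)-S/T occurrences, overlaps allowed."""
    sequence = sequence.upper()
    return [
        SequonHit(m.start() + numbering_start, m.group(1), source)
        for m in _SEQUON_RE.finditer(sequence)
    ]


_AA_3TO1 = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}


def chain_sequence(chain: Chain) -> tuple[str, int]:
    """One-letter sequence read off a chain's residue names, plus the
    numbering of its first residue.  Non-standard residues become X."""
    polymer = chain.polymer()
    if not polymer:
        raise ValueError(f"chain {chain.chain_id} has no polymer residues")
    seq = "".join(_AA_3TO1.get(r.name, "X") for r in polymer)
    return seq, polymer[0].seq_position


# ---------------------------------------------------------------------------
# Glycan trees

#: monosaccharide classification by residue name
SUGAR_TYPES = {
    "NAG": "GlcNAc", "NDG": "GlcNAc",
    "MAN": "Man", "BMA": "Man",
    "GLC": "Glc", "BGC": "Glc",
    # 6-sulfoquinovose under the component codes seen for sulfonated hexoses
    "SQV": "sulfoquinovose", "G6S": "sulfoquinovose", "SGA": "sulfoquinovose",
}

#: the confirmed hexasaccharide composition of the S. acidocaldarius N-glycan
COMPLETE_COMPOSITION = {"GlcNAc": 2, "Man": 2, "Glc": 1, "sulfoquinovose": 1}


@dataclass
class GlycanTree:
    chain_id: str
    asn_position: int
    residues: list[tuple[int, str]]  # (seq_position, residue_name), BFS order from the Asn
    edges: list[tuple[tuple[str, int], tuple[str, int]]]
    counts: dict[str, int] = field(default_factory=dict)
    complete: bool = False
    branch_position: int | None = None  # seq_position of the branching second GlcNAc

    @property
    def n_sugars(self) -> int:
        return len(self.residues)


def validate_glycans(model: StructureModel) -> list[GlycanTree]:
    """Traverse explicit linkage records into per-site rooted glycan trees.

    Each glycosylated Asn roots the connected component of hetero sugar
    residues reachable through the model's connectivity records.  The tree
    is complete when it carries the hexasaccharide composition (2 GlcNAc,
    2 Man, 1 Glc, 1 sulfoquinovose); sugar components not attached to any
    Asn are reported as orphans via a warning.
    """
    node = {}  # (chain_id, seq_position) -> Residue
    for chain in model.chains:
        for res in chain.residues:
            node[(chain.chain_id, res.seq_position)] = res
    adjacency: dict[tuple[str, int], set[tuple[str, int]]] = {}
    for con in model.connections:
        a, b = (con.chain1, con.res1), (con.chain2, con.res2)
        if a in node and b in node:
            adjacency.setdefault(a, set()).add(b)
            adjacency.setdefault(b, set()).add(a)

    def is_sugar(key) -> bool:
        res = node[key]
        return res.hetero and res.name in SUGAR_TYPES

    trees = []
    rooted_sugars: set[tuple[str, int]] = set()
    for chain in model.chains:
        for res in chain.polymer():
            if res.name != "ASN":
                continue
            root = (chain.chain_id, res.seq_position)
            first = [k for k in adjacency.get(root, ()) if is_sugar(k)]
            if not first:
                continue
            visited = {root}
            order: list[tuple[str, int]] = []
            edges = []
            children: dict[tuple[str, int], list] = {}
            queue = deque([root])
            while queue:
                cur = queue.popleft()
                for nxt in sorted(adjacency.get(cur, ())):
                    if nxt in visited or not is_sugar(nxt):
                        continue
                    visited.add(nxt)
                    order.append(nxt)
                    edges.append((cur, nxt))
                    children.setdefault(cur, []).append(nxt)
                    queue.append(nxt)
            rooted_sugars |= set(order)
            counts: dict[str, int] = {}
            for key in order:
                t = SUGAR_TYPES[node[key].name]
                counts[t] = counts.get(t, 0) + 1
            complete = counts == COMPLETE_COMPOSITION
            branch = None
            glcnacs = [k for k in order if SUGAR_TYPES[node[k].name] == "GlcNAc"]
            if len(glcnacs) >= 2 and len(children.get(glcnacs[1], [])) >= 2:
                branch = glcnacs[1][1]
            trees.append(
                GlycanTree(
                    chain_id=chain.chain_id,
                    asn_position=res.seq_position,
                    residues=[(k[1], node[k].name) for k in order],
                    edges=edges,
                    counts=counts,
                    complete=complete,
                    branch_position=branch,
                )
            )
    orphans = {
        (c.chain_id, r.seq_position)
        for c in model.chains
        for r in c.residues
        if r.hetero and r.name in SUGAR_TYPES
    } - rooted_sugars
    if orphans:
        logger.warning("%d sugar residues not attached to any Asn: %s", len(orphans), sorted(orphans))
    return trees


# ---------------------------------------------------------------------------
# Diameter


def measure_diameter(
    model: StructureModel,
    indexing: SubunitIndexing | None = None,
    atom_set: str = "protein",
    percentile: float = 99.0,
) -> float:
    """Filament width: 2 × the given percentile of radial atom distances.

    The percentile (default 99) resists single outlier atoms.  atom_set
    "protein" uses polymer atoms only, "all" includes glycans and ligands.
    """
    if atom_set not in ("protein", "all"):
        raise ValueError("atom_set must be 'protein' or 'all'")
    if indexing is not None:
        axis_point, axis_dir = indexing.axis_point, indexing.axis_dir
    else:
        try:
            from .helix import axis_from_centroids

            axis_point, axis_dir = axis_from_centroids(model)
        except ValueError:
            pts = model.coords(hetero=(atom_set == "all"))
            axis_point = pts.mean(axis=0)
            axis_dir = np.array([0.0, 0.0, 1.0])
    pts = model.coords(hetero=(atom_set == "all"))
    if len(pts) == 0:
        raise ValueError("no atoms selected")
    rel = pts - axis_point
    radial = rel - np.outer(rel @ axis_dir, axis_dir)
    r = np.linalg.norm(radial, axis=1)
    return float(2.0 * np.percentile(r, percentile))
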