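"""Synthetic inputs with exact ground truth.

Three generators cover every input the pipeline needs:

* a decoy proteome with one planted target subunit sequence,
* noisy per-position residue-class observations of that target, emulating
  what is readable from a 3.0–3.5 Å map,
* a coarse pseudo-atom filament built by a helical screw operator, with
  plantable inter-subunit tail contacts (donor strand complementation) and
  an isopeptide-geometry pseudo-bond.

Every generator is a pure function of (spec, seed) and records its planted
features in a manifest so that detector tests have exact ground truth.

The canonical synthetic target (:func:`thread_target_sequence`) is a 206-
residue mature subunit numbered from Asp24, carrying N-glycosylation
sequons at N56, N80, N83, N121 and N146 and an Asn at position 57 — the
positions the thread subunit architecture is defined by.  It is a synthetic
stand-in, not the real Saci_0406 sequence.
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass, field

import numpy as np

from .fingerprint import CLASS_MEMBERS, ClassObservation
from .helix import HelicalOperator
from .io import Atom, Chain, Connection, ProteomeRecord, Residue, StructureModel

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

AA_1TO3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

#: mature-protein numbering starts after the signal peptidase I site (Ala23/Asp24)
MATURE_START = 24
TARGET_LENGTH = 206
#: mature positions of the five planted N-glycosylation sequon asparagines
SEQUON_POSITIONS = (56, 80, 83, 121, 146)
#: mature position of the planted isopeptide donor asparagine
ISOPEPTIDE_DONOR = 57

# roughly protein-like background used for the canonical target
_TARGET_COMPOSITION = {
    "A": 0.082, "C": 0.014, "D": 0.054, "E": 0.067, "F": 0.039,
    "G": 0.071, "H": 0.023, "I": 0.059, "K": 0.058, "L": 0.097,
    "M": 0.024, "N": 0.041, "P": 0.047, "Q": 0.039, "R": 0.055,
    "S": 0.066, "T": 0.053, "V": 0.069, "W": 0.011, "Y": 0.031,
}

_SEQUON_RE = re.compile(r"(?=(N[^P][ST]))")


@functools.lru_cache(maxsize=1)
def thread_target_sequence() -> str:
    """The canonical synthetic mature thread-subunit sequence (length 206).

    Deterministic: starts with Asp24 (the mature N-terminus left by signal
    peptidase I) and an early YYY aromatic motif, carries exactly the five
    sequons N56/N80/N83/N121/N146 with Asn57 at the X position of the first
    one, and no other N-x(≠P)-S/T sequon anywhere.
    """
    rng = np.random.default_rng(740624)
    letters = np.array(list(AA_LETTERS))
    probs = np.array([_TARGET_COMPOSITION[a] for a in AA_LETTERS])
    probs = probs / probs.sum()
    seq = list(rng.choice(letters, size=TARGET_LENGTH, p=probs))
    seq[0:7] = list("DVKYYYA")
    protected: set[int] = set()
    for pos in SEQUON_POSITIONS:
        i = pos - MATURE_START
        seq[i] = "N"
        if seq[i + 1] == "P":
            seq[i + 1] = "A"
        seq[i + 2] = "T"
        protected |= {i, i + 1, i + 2}
    seq[ISOPEPTIDE_DONOR - MATURE_START] = "N"
    planted = {p - MATURE_START for p in SEQUON_POSITIONS}
    for _ in range(100):
        s = "".join(seq)
        accidental = [m.start() for m in _SEQUON_RE.finditer(s) if m.start() not in planted]
        if not accidental:
            break
        j = accidental[0]
        if j + 2 not in protected:
            seq[j + 2] = "A"
        elif j not in protected:
            seq[j] = "Q"
        else:
            seq[j + 1] = "P"  # x=P kills the sequon without touching N or S/T
    s = "".join(seq)
    found = {m.start() + MATURE_START for m in _SEQUON_RE.finditer(s)}
    assert found == set(SEQUON_POSITIONS), "sequon planting failed"
    return s


# ---------------------------------------------------------------------------
# Proteome generator


@dataclass
class ProteomeSpec:
    n_decoys: int = 1000
    length_min: int = 100
    length_max: int = 300
    composition: dict[str, float] | None = None  # default uniform 0.05
    target: str | None = None  # default thread_target_sequence()
    target_id: str = "target"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be >= 0")
        if self.composition is not None:
            total = sum(self.composition.values())
            if total == 0:
                raise ValueError("degenerate composition: probabilities sum to 0")
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"composition sums to {total}, not 1")
            if any(v < 0 for v in self.composition.values()):
                raise ValueError("negative composition probability")


def gen_proteome(spec: ProteomeSpec) -> tuple[list[ProteomeRecord], dict]:
    """Decoy proteome with the target planted at a seeded random rank.

    Decoys are i.i.d. draws from the background composition with uniform
    lengths in [length_min, length_max].  The manifest records the target id,
    its rank, and all sequence lengths.
    """
    rng = np.random.default_rng(spec.seed)
    letters = np.array(list(AA_LETTERS))
    comp = spec.composition or {a: 0.05 for a in AA_LETTERS}
    probs = np.array([comp.get(a, 0.0) for a in AA_LETTERS])
    target = spec.target if spec.target is not None else thread_target_sequence()
    records = []
    for i in range(spec.n_decoys):
        length = int(rng.integers(spec.length_min, spec.length_max + 1))
        seq = "".join(rng.choice(letters, size=length, p=probs))
        records.append(ProteomeRecord(f"decoy_{i:04d}", "synthetic decoy", seq))
    rank = int(rng.integers(0, len(records) + 1))
    records.insert(rank, ProteomeRecord(spec.target_id, "planted target", target))
    manifest = {
        "target_id": spec.target_id,
        "target_rank": rank,
        "n_records": len(records),
        "lengths": {r.id: len(r.sequence) for r in records},
        "seed": spec.seed,
    }
    return records, manifest


# ---------------------------------------------------------------------------
# Observation generator


@dataclass
class ObservationSpec:
    """Noise model for what a 3.0–3.5 Å map lets one read per position.

    ``emission`` maps each observable class (SEQUON covers the whole
    N-x-S/T triplet as a unit) to the probability that a true instance is
    observed as that class rather than UNK; ``misassignment_rate`` is the
    probability that a position's class is replaced by a wrong one.  The
    inward-pointing mask (residues facing the β-barrel core, readable as
    aliphatic) is drawn at the given fraction unless supplied explicitly.
    """

    emission: dict[str, float] | float = field(
        default_factory=lambda: {
            "ARO": 0.9, "PRO": 0.9, "GLY": 0.8,
            "SEQUON": 0.9, "ALI_IN": 0.8, "SML_SURF": 0.7,
        }
    )
    misassignment_rate: float = 0.05
    inward_fraction: float = 0.3
    inward_mask: frozenset[int] | None = None  # 0-based positions
    seed: int = 0

    def __post_init__(self) -> None:
        keys = ("ARO", "PRO", "GLY", "SEQUON", "ALI_IN", "SML_SURF")
        if isinstance(self.emission, (int, float)):
            self.emission = {k: float(self.emission) for k in keys}
        for k in keys:
            self.emission.setdefault(k, 0.0)
        for k, v in self.emission.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"emission[{k}]={v} outside [0, 1]")
        if not 0.0 <= self.misassignment_rate <= 1.0:
            raise ValueError("misassignment_rate outside [0, 1]")
        if not 0.0 <= self.inward_fraction <= 1.0:
            raise ValueError("inward_fraction outside [0, 1]")


_ASSIGNABLE = ("ARO", "PRO", "GLY", "SEQ_N", "SEQ_X", "SEQ_ST", "ALI_IN", "SML_SURF")


def gen_observations(sequence: str, spec: ObservationSpec) -> list[ClassObservation]:
    """One noisy class observation per position of ``sequence``.

    Assignment order mirrors how features dominate a map: glycan-marked
    sequon triplets first, then uniquely shaped ARO/PRO/GLY side chains,
    then inward aliphatics and short surface residues; everything else is
    UNK.  Misassignment noise is applied last.  Deterministic per seed.
    """
    sequence = sequence.upper()
    bad = set(sequence) - set(AA_LETTERS)
    if bad:
        raise ValueError(f"non-canonical letters {sorted(bad)}")
    rng = np.random.default_rng(spec.seed)
    em = spec.emission
    n = len(sequence)
    labels: list[str | None] = [None] * n
    for m in _SEQUON_RE.finditer(sequence):
        i = m.start()
        if any(labels[i + t] is not None for t in range(3)):
            continue  # first triplet wins on overlap
        if rng.random() < em["SEQUON"]:
            labels[i], labels[i + 1], labels[i + 2] = "SEQ_N", "SEQ_X", "SEQ_ST"
    for i, aa in enumerate(sequence):
        if labels[i] is not None:
            continue
        if aa in "FYW" and rng.random() < em["ARO"]:
            labels[i] = "ARO"
        elif aa == "P" and rng.random() < em["PRO"]:
            labels[i] = "PRO"
        elif aa == "G" and rng.random() < em["GLY"]:
            labels[i] = "GLY"
    if spec.inward_mask is not None:
        mask = set(spec.inward_mask)
    else:
        k = round(spec.inward_fraction * n)
        mask = set(rng.choice(n, size=k, replace=False).tolist()) if k else set()
    for i, aa in enumerate(sequence):
        if labels[i] is not None:
            continue
        if i in mask:
            if aa in "LIV" and rng.random() < em["ALI_IN"]:
                labels[i] = "ALI_IN"
        elif aa in "NSD" and rng.random() < em["SML_SURF"]:
            labels[i] = "SML_SURF"
    out = []
    for i in range(n):
        lab = labels[i] or "UNK"
        if spec.misassignment_rate and rng.random() < spec.misassignment_rate:
            choices = [c for c in _ASSIGNABLE if c != lab]
            lab = choices[int(rng.integers(len(choices)))]
        out.append(ClassObservation(i + 1, lab))
    return out


# ---------------------------------------------------------------------------
# Filament generator


@dataclass
class FilamentSpec:
    """Coarse filament: pseudo-atom subunits stacked by a screw operator.

    Each residue carries three pseudo-atoms (backbone N and CA plus one
    side-chain atom SC).  The head is a ring of stated radius whose centroid
    is displaced radially from the helical axis; the tail (the first
    ``tail_length`` residues) is routed toward where the subunits at the
    planted contact offsets sit, deepest contact first, mirroring a
    donor-strand tail buried in the n−1 and n−2 neighbours.
    """

    operator: HelicalOperator = field(
        default_factory=lambda: HelicalOperator(twist=-103.234, rise=31.649)
    )
    n_subunits: int = 6
    head_radius: float = 14.0
    head_offset: float = 6.0  # radial displacement of the head centroid from the axis
    tail_length: int = 10
    sigma: float = 0.1  # per-atom isotropic coordinate noise, Å
    isopeptide: tuple[int, int] | None = (ISOPEPTIDE_DONOR, 2)  # (donor seq_position, offset k)
    tail_contacts: frozenset[int] | None = frozenset({1, 2})
    sequence: str | None = None  # default thread_target_sequence()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subunits < 1:
            raise ValueError("n_subunits must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.isopeptide is not None and self.isopeptide[1] < 1:
            raise ValueError("isopeptide acceptor offset must be >= 1")
        if self.tail_contacts is not None:
            self.tail_contacts = frozenset(self.tail_contacts)
            if any(k < 1 for k in self.tail_contacts):
                raise ValueError("tail contact offsets must be >= 1")


def gen_filament(spec: FilamentSpec) -> tuple[StructureModel, dict]:
    """Generate a coarse filament and its ground-truth manifest.

    Subunit 0 is built in the axis frame (+z axis through the origin),
    subunits 1..n−1 by repeated application of the operator, so at σ=0 all
    chains are exact rigid transforms of each other.  If an isopeptide is
    planted, the donor residue's SC atom of subunit i is placed exactly
    1.33 Å from the backbone nitrogen of the first residue of subunit i+k,
    coplanar with the flanking CA atoms (planar amide geometry); this
    covalent constraint is re-imposed after the coordinate noise, which is
    otherwise added to every atom independently.
    """
    seq = spec.sequence if spec.sequence is not None else thread_target_sequence()
    L = len(seq)
    if spec.tail_length >= L:
        raise ValueError("tail_length must be smaller than the sequence length")
    rng = np.random.default_rng(spec.seed)
    op = spec.operator
    n_head = L - spec.tail_length
    theta = 2 * np.pi * np.arange(n_head) / n_head
    u1 = np.array([1.0, 0.0, 0.0])
    u2 = np.array([0.0, 0.0, 1.0])
    center = spec.head_offset * u1
    outward = np.outer(np.cos(theta), u1) + np.outer(np.sin(theta), u2)  # (n_head, 3)
    tangent = -np.outer(np.sin(theta), u1) + np.outer(np.cos(theta), u2)
    head_ca = center + spec.head_radius * outward
    head_n = head_ca + 1.2 * tangent
    head_sc = head_ca - 1.5 * outward  # inward, toward the ring centre

    # tail routing: residue i of the tail targets a head atom of the subunit
    # `offset` below, deepest offset first (the N-terminus reaches furthest)
    offsets = sorted(spec.tail_contacts, reverse=True) if spec.tail_contacts else []
    tail_atoms = []  # (n_xyz, ca_xyz, sc_xyz) in subunit-0 frame
    tail_offset_of: list[int | None] = []
    n_groups = max(len(offsets), 1)
    group_size = spec.tail_length // n_groups if offsets else spec.tail_length
    stride = min(16, max(1, (n_head // n_groups - 1) // max(group_size, 1)))
    for i in range(spec.tail_length):
        if offsets:
            g = min(i // group_size, len(offsets) - 1)
            k = offsets[g]
            j = (g * (n_head // n_groups) + (i - g * group_size) * stride) % n_head
            ca = head_ca[j] + 2.5 * outward[j]
            sc = head_ca[j] + 4.0 * outward[j]
            npos = ca + 1.2 * tangent[j]
            rot_inv, trans_inv = op.matrix(-k)
            tail_atoms.append(tuple(rot_inv @ p + trans_inv for p in (npos, ca, sc)))
            tail_offset_of.append(k)
        else:
            # no planted contacts: dangle the tail straight down the axis
            ca = center + np.array([0.0, 0.0, -spec.head_radius - 3.0 * (spec.tail_length - i)])
            tail_atoms.append((ca + np.array([0.0, 1.2, 0.0]), ca, ca + np.array([1.5, 0.0, 0.0])))
            tail_offset_of.append(None)

    residues0 = []
    for i in range(L):
        if i < spec.tail_length:
            npos, ca, sc = tail_atoms[i]
        else:
            j = i - spec.tail_length
            npos, ca, sc = head_n[j], head_ca[j], head_sc[j]
        residues0.append(
            Residue(
                seq_position=MATURE_START + i,
                name=AA_1TO3[seq[i]],
                atoms=[
                    Atom("N", "N", np.array(npos, dtype=float)),
                    Atom("CA", "C", np.array(ca, dtype=float)),
                    Atom("SC", "C", np.array(sc, dtype=float)),
                ],
            )
        )

    # plant the isopeptide donor SC in the subunit-0 frame: 1.33 Å from the
    # acceptor nitrogen of subunit +k, coplanar with both CA atoms
    iso = spec.isopeptide
    if iso is not None:
        donor_pos, k = iso
        donor_idx = donor_pos - MATURE_START
        if not 0 <= donor_idx < L:
            raise ValueError(f"isopeptide donor {donor_pos} outside the modelled range")
        rot_k, trans_k = op.matrix(k)
        n_acc = rot_k @ residues0[0].atom("N").xyz + trans_k
        ca_acc = rot_k @ residues0[0].atom("CA").xyz + trans_k
        ca_don = residues0[donor_idx].atom("CA").xyz
        residues0[donor_idx].atom("SC").xyz = _amide_placement(n_acc, ca_acc, ca_don)

    from .helix import apply_operator  # local import to avoid a cycle at module load

    model = apply_operator(StructureModel([Chain("A", residues0)]), op, spec.n_subunits)
    if spec.sigma > 0:
        for chain in model.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    atom.xyz = atom.xyz + rng.normal(0.0, spec.sigma, size=3)
    n_bonds = 0
    if iso is not None:
        donor_pos, k = iso
        donor_idx = donor_pos - MATURE_START
        for i in range(spec.n_subunits - k):
            donor_chain, acc_chain = model.chains[i], model.chains[i + k]
            n_acc = acc_chain.residues[0].atom("N").xyz
            ca_acc = acc_chain.residues[0].atom("CA").xyz
            ca_don = donor_chain.residues[donor_idx].atom("CA").xyz
            donor_chain.residues[donor_idx].atom("SC").xyz = _amide_placement(n_acc, ca_acc, ca_don)
            n_bonds += 1

    manifest = {
        "twist": op.twist,
        "rise": op.rise,
        "n_subunits": spec.n_subunits,
        "sequence_length": L,
        "numbering_start": MATURE_START,
        "tail_residues": [MATURE_START, MATURE_START + spec.tail_length - 1],
        "tail_contact_offsets": sorted(spec.tail_contacts) if spec.tail_contacts else [],
        "tail_offset_per_residue": tail_offset_of,
        "isopeptide": {"donor": iso[0], "offset": iso[1], "n_bonds": n_bonds} if iso else None,
        "sigma": spec.sigma,
        "seed": spec.seed,
    }
    return model, manifest


#: the confirmed hexasaccharide, root-first; the second GlcNAc is the branch point
REFERENCE_GLYCAN = ("NAG", "NAG", "MAN", "MAN", "GLC", "SQV")


def attach_reference_glycans(
    model: StructureModel, chain_id: str, sites: list[int] | None = None
) -> StructureModel:
    """Decorate sequon asparagines with the reference hexasaccharide topology.

    Adds hetero sugar residues (2 GlcNAc in series, the second branching to
    2 Man, 1 Glc and 1 sulfoquinovose) plus the explicit linkage records the
    glycan validator consumes.  Coordinates are placeholders stepped away
    from each Asn — this decorates connectivity, it does not simulate glycan
    geometry.  Returns a decorated copy; sites default to every sequon Asn
    read off the chain's residue names.
    """
    from .architecture import chain_sequence, scan_sequons

    out = model.copy()
    chain = out.chain(chain_id)
    if sites is None:
        seq, start = chain_sequence(chain)
        sites = [h.position for h in scan_sequons(seq, numbering_start=start)]
    next_pos = max((r.seq_position for c in out.chains for r in c.residues), default=0) + 1
    for site in sites:
        asn = next(r for r in chain.polymer() if r.seq_position == site)
        if asn.name != "ASN":
            raise ValueError(f"residue {site} in chain {chain_id} is {asn.name}, not ASN")
        anchor = asn.atom("ND2") or asn.atom("SC") or asn.atoms[-1]
        positions = []
        for i, name in enumerate(REFERENCE_GLYCAN):
            xyz = anchor.xyz + np.array([0.0, 0.0, 0.0]) + (i + 1) * np.array([1.5, 0.9, 0.3])
            pos = next_pos
            next_pos += 1
            chain.residues.append(
                Residue(pos, name, [Atom("C1", "C", xyz)], hetero=True)
            )
            positions.append(pos)
        out.connections.append(
            Connection(chain_id, site, anchor.name, chain_id, positions[0], "C1")
        )
        out.connections.append(
            Connection(chain_id, positions[0], "C1", chain_id, positions[1], "C1")
        )
        for pos in positions[2:]:
            out.connections.append(
                Connection(chain_id, positions[1], "C1", chain_id, pos, "C1")
            )
    return out


def _amide_placement(n_acc: np.ndarray, ca_acc: np.ndarray, ca_don: np.ndarray) -> np.ndarray:
    """A point 1.33 Å from the acceptor N, in the plane of the flanking CAs."""
    v1 = ca_don - n_acc
    v2 = ca_acc - n_acc
    u = v1 / np.linalg.norm(v1) + v2 / np.linalg.norm(v2)
    norm = np.linalg.norm(u)
    if norm < 1e-9:  # anti-parallel degenerate case: fall back to the donor direction
        u, norm = v1, np.linalg.norm(v1)
    return n_acc + 1.33 * u / norm
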