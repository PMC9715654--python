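"""Structure, sequence and configuration I/O.

All coordinates are carried in Å throughout the package; residue numbering
is taken verbatim from the file (mature thread subunits start at Asp24), and
hetero residues (glycans, ligands) are retained together with the explicit
connectivity records (LINK / struct_conn) that attach them.
"""

from __future__ import annotations

import logging
import sys
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np
from Bio import SeqIO

logger = logging.getLogger("threadarch")

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")


def setup_logging(level: str = "INFO") -> None:
    """Configure package logging to standard error."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(getattr(logging, level.upper()))


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray  # shape (3,), Å

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)


@dataclass
class Residue:
    seq_position: int
    name: str  # 3-letter code
    atoms: list[Atom]
    hetero: bool = False

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue]

    def polymer(self) -> list[Residue]:
        return [r for r in self.residues if not r.hetero]

    def coords(self, atom_names: set[str] | None = None, hetero: bool = True) -> np.ndarray:
        pts = [
            a.xyz
            for r in self.residues
            if hetero or not r.hetero
            for a in r.atoms
            if atom_names is None or a.name in atom_names
        ]
        return np.array(pts, dtype=float).reshape(-1, 3)


@dataclass
class Connection:
    """Explicit inter-residue link (LINK record / struct_conn row)."""

    chain1: str
    res1: int
    atom1: str
    chain2: str
    res2: int
    atom2: str


@dataclass
class StructureModel:
    chains: list[Chain]
    connections: list[Connection] = field(default_factory=list)

    def validate(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate chain ids: {ids}")
        for chain in self.chains:
            positions = [r.seq_position for r in chain.residues if not r.hetero]
            if any(b <= a for a, b in zip(positions, positions[1:])):
                raise ValueError(
                    f"chain {chain.chain_id}: polymer seq_positions not strictly increasing"
                )
            for r in chain.residues:
                for a in r.atoms:
                    if not np.all(np.isfinite(a.xyz)):
                        raise ValueError(
                            f"non-finite coordinates at {chain.chain_id}/{r.seq_position}/{a.name}"
                        )

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}")

    def coords(self, atom_names: set[str] | None = None, hetero: bool = True) -> np.ndarray:
        if not self.chains:
            return np.empty((0, 3))
        return np.vstack([c.coords(atom_names, hetero) for c in self.chains])

    def copy(self) -> "StructureModel":
        return StructureModel(
            chains=[
                Chain(
                    c.chain_id,
                    [
                        Residue(r.seq_position, r.name, [Atom(a.name, a.element, a.xyz.copy()) for a in r.atoms], r.hetero)
                        for r in c.residues
                    ],
                )
                for c in self.chains
            ],
            connections=[replace(k) for k in self.connections],
        )


@dataclass
class ProteomeRecord:
    id: str
    description: str
    sequence: str
    has_unknown: bool = False  # sequence contains X


# ---------------------------------------------------------------------------
# Structure I/O (gemmi-backed)


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("pdb", "mmcif"):
            raise ValueError(f"unknown structure format {format!r}; use 'pdb' or 'mmcif'")
        return format
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        return "pdb"
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format='pdb'|'mmcif'")


def read_structure(path: str | Path, format: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    All polymer and hetero residues are retained in file order; coordinates
    are in Å and residue numbering is verbatim.  Connectivity records
    (LINK / struct_conn) are parsed into :class:`Connection` entries.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"failed to parse {path.name} as {fmt}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path.name}: no models found")
    model = st[0]
    chains = []
    for ch in model:
        residues = []
        for res in ch:
            atoms = [Atom(a.name, a.element.name, np.array([a.pos.x, a.pos.y, a.pos.z])) for a in res]
            residues.append(
                Residue(
                    seq_position=res.seqid.num,
                    name=res.name,
                    atoms=atoms,
                    hetero=res.het_flag == "H",
                )
            )
        chains.append(Chain(ch.name, residues))
    connections = []
    for con in st.connections:
        p1, p2 = con.partner1, con.partner2
        connections.append(
            Connection(
                p1.chain_name, p1.res_id.seqid.num, p1.atom_name,
                p2.chain_name, p2.res_id.seqid.num, p2.atom_name,
            )
        )
    out = StructureModel(chains, connections)
    out.validate()
    return out


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "threadarch"
    gm = gemmi.Model("1")
    for chain in model.chains:
        gc = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(res.seq_position, " ")
            gr.het_flag = "H" if res.hetero else "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.xyz)
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    for con in model.connections:
        gcon = gemmi.Connection()
        gcon.type = gemmi.ConnectionType.Covale
        gcon.partner1 = gemmi.make_address(
            st[0][con.chain1], _find_res(st[0][con.chain1], con.res1), _find_atom(st, con.chain1, con.res1, con.atom1)
        )
        gcon.partner2 = gemmi.make_address(
            st[0][con.chain2], _find_res(st[0][con.chain2], con.res2), _find_atom(st, con.chain2, con.res2, con.atom2)
        )
        st.connections.append(gcon)
    st.setup_entities()
    return st


def _find_res(gchain: gemmi.Chain, seqnum: int) -> gemmi.Residue:
    for r in gchain:
        if r.seqid.num == seqnum:
            return r
    raise KeyError(f"residue {seqnum} not in chain {gchain.name}")


def _find_atom(st: gemmi.Structure, chain: str, seqnum: int, name: str) -> gemmi.Atom:
    res = _find_res(st[0][chain], seqnum)
    for a in res:
        if a.name == name:
            return a
    raise KeyError(f"atom {name} not in {chain}/{seqnum}")


def write_structure(model: StructureModel, path: str | Path, format: str | None = None) -> None:
    """Write a StructureModel to PDB (default) or mmCIF."""
    path = Path(path)
    fmt = _infer_format(path, format)
    model.validate()
    if fmt == "pdb" and any(len(c.chain_id) > 1 for c in model.chains):
        raise ValueError("PDB format cannot hold multi-character chain ids; write mmCIF")
    st = _to_gemmi(model)
    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path) -> list[ProteomeRecord]:
    """Read a protein FASTA into ProteomeRecords.

    Sequences are uppercased and checked against the canonical 20-letter
    alphabet; X is permitted but flagged, gap characters are rejected, and
    duplicate ids raise.
    """
    path = Path(path)
    records = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path.name}: record {rec.id!r} has empty sequence")
        if "-" in seq or "." in seq:
            raise ValueError(f"{path.name}: record {rec.id!r} contains gap characters")
        bad = set(seq) - CANONICAL_AA - {"X"}
        if bad:
            raise ValueError(f"{path.name}: record {rec.id!r} has non-canonical letters {sorted(bad)}")
        seen[rec.id] = seen.get(rec.id, 0) + 1
        records.append(ProteomeRecord(rec.id, rec.description, seq, has_unknown="X" in seq))
    if not records:
        raise ValueError(f"{path.name}: empty FASTA")
    dups = sorted(i for i, n in seen.items() if n > 1)
    if dups:
        raise ValueError(f"{path.name}: duplicate ids {dups}")
    return records


def write_fasta(records: list[ProteomeRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description.startswith(rec.id) else f"{rec.id} {rec.description}".strip()
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class RunConfig:
    """Every tunable used anywhere in the pipeline, with its default.

    Scoring parameters are in bits; geometric cutoffs in Å / degrees.
    """

    seed: int = 0
    log_level: str = "INFO"
    # scoring (proteome search)
    gap_open: float = 11.0
    gap_extend: float = 1.0
    mismatch: float = -4.0
    score_scale: float = 1.0
    evalue_threshold: float = 0.01
    n_shuffles: int = 100
    # geometry (architecture detectors)
    tail_length: int = 10
    contact_cutoff: float = 4.5
    dsc_min_fraction: float = 0.2
    bond_cutoff: float = 1.8
    survey_bond_cutoff: float = 2.5
    planarity_max_deg: float = 30.0
    hbond_cutoff: float = 3.5
    # helical search grid
    twist_step: float = 1.0
    rise_step: float = 0.5
    refine_factor: int = 10
    superpose_rmsd_warn: float = 5.0

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def override(self, **kwargs) -> "RunConfig":
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **updates)
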