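"""Degenerate residue-class queries read from a density-map fingerprint.

At 3.0–3.5 Å resolution only some side chains are identifiable from shape
alone: aromatics (F/Y/W), prolines and low-density glycines, plus the
positions of N-glycan trees which mark N-x(≠P)-S/T sequons.  Medium inward-
pointing residues are readable as "aliphatic" (L/I/V) and short surface
residues as N/S/D.  This module encodes those observation classes and turns
per-position observations into a degenerate query for proteome search, or
collapses the query to a single concrete sequence for export to external
search tools.

Histidine is deliberately excluded from the aromatic class: its ring is not
uniquely shaped at this resolution.  The sequon X position excludes proline,
following the standard N-glycosylation consensus.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .io import CANONICAL_AA, logger

ALL20 = frozenset(CANONICAL_AA)

#: The nine observation classes and their amino-acid member sets.
CLASS_MEMBERS: dict[str, frozenset[str]] = {
    "ARO": frozenset("FYW"),
    "PRO": frozenset("P"),
    "GLY": frozenset("G"),
    "SEQ_N": frozenset("N"),
    "SEQ_X": ALL20 - frozenset("P"),
    "SEQ_ST": frozenset("ST"),
    "ALI_IN": frozenset("LIV"),
    "SML_SURF": frozenset("NSD"),
    "UNK": ALL20,
}

CLASS_LABELS = tuple(CLASS_MEMBERS)

#: Default one-letter representative used when a query is concretized.
CONCRETIZE_DEFAULT: dict[str, str] = {
    "ARO": "F",
    "PRO": "P",
    "GLY": "G",
    "SEQ_N": "N",
    "SEQ_X": "A",
    "SEQ_ST": "T",
    "ALI_IN": "L",
    "SML_SURF": "S",
    "UNK": "A",
}


@dataclass
class ClassObservation:
    """One per-position piece of evidence read from the map."""

    position: int  # 1-based along the traced backbone
    label: str
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in CLASS_MEMBERS:
            raise ValueError(f"unknown class label {self.label!r}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass
class DegenerateQuery:
    """An ordered run of residue-class labels, one per backbone position."""

    labels: list[str]
    confidences: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        for lab in self.labels:
            if lab not in CLASS_MEMBERS:
                raise ValueError(f"unknown class label {lab!r}")
        if not self.confidences:
            self.confidences = [1.0] * len(self.labels)

    def __len__(self) -> int:
        return len(self.labels)


def build_query(observations: list[ClassObservation], fill_gaps: bool = False) -> DegenerateQuery:
    """Assemble per-position observations into a degenerate query.

    Positions must form a gap-free 1..L run unless ``fill_gaps`` is set, in
    which case missing positions become UNK.  Sequon triplets are validated
    (SEQ_N should be followed by SEQ_X then SEQ_ST); violations are kept as
    observed but logged.
    """
    if not observations:
        raise ValueError("no observations")
    by_pos: dict[int, ClassObservation] = {}
    for obs in observations:
        if obs.position in by_pos:
            raise ValueError(f"duplicate observation at position {obs.position}")
        by_pos[obs.position] = obs
    length = max(by_pos)
    missing = [p for p in range(1, length + 1) if p not in by_pos]
    if missing and not fill_gaps:
        raise ValueError(
            f"observations do not cover 1..{length} (first gap at {missing[0]}); "
            "fill missing positions as UNK or pass fill_gaps=True"
        )
    labels, confs = [], []
    for p in range(1, length + 1):
        obs = by_pos.get(p)
        labels.append(obs.label if obs else "UNK")
        confs.append(obs.confidence if obs else 1.0)
    for i, lab in enumerate(labels):
        if lab == "SEQ_N":
            nxt = labels[i + 1] if i + 1 < len(labels) else None
            nxt2 = labels[i + 2] if i + 2 < len(labels) else None
            if nxt != "SEQ_X" or nxt2 != "SEQ_ST":
                logger.warning(
                    "SEQ_N at position %d not followed by SEQ_X, SEQ_ST (got %s, %s); kept as observed",
                    i + 1, nxt, nxt2,
                )
    return DegenerateQuery(labels, confs)


def concretize_query(query: DegenerateQuery, policy: dict[str, str] | None = None) -> str:
    """Collapse a degenerate query to one representative letter per class.

    The default policy mirrors manual model building: UNK and sequon-X
    positions become alanine, aliphatics leucine, surface residues serine.
    The output is class-consistent and suitable for FASTA export.
    """
    if len(query) == 0:
        raise ValueError("empty query")
    pol = dict(CONCRETIZE_DEFAULT)
    if policy:
        pol.update(policy)
    for label, letter in pol.items():
        if letter not in CLASS_MEMBERS[label]:
            raise ValueError(f"policy letter {letter!r} is not a member of class {label}")
    return "".join(pol[lab] for lab in query.labels)


# ---------------------------------------------------------------------------
# Observation TSV round-trip


def read_observations(path: str | Path) -> list[ClassObservation]:
    """Read a ``position<TAB>class<TAB>confidence`` table (header required)."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"position", "class", "confidence"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"observation TSV must have columns {sorted(required)}")
        out = [
            ClassObservation(int(row["position"]), row["class"], float(row["confidence"]))
            for row in reader
        ]
    if not out:
        raise ValueError(f"{path}: no observations")
    return out


def write_observations(observations: list[ClassObservation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["position", "class", "confidence"])
        for obs in observations:
            writer.writerow([obs.position, obs.label, f"{obs.confidence:g}"])
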