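"""Subunit indexing, DSC, isopeptide, sequon, glycan and diameter detectors."""

import logging
import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from threadarch import (
    FilamentSpec,
    HelicalOperator,
    detect_dsc,
    detect_isopeptide,
    gen_filament,
    index_subunits,
    measure_diameter,
    scan_sequons,
    validate_glycans,
)
from threadarch.architecture import chain_sequence
from threadarch.io import Atom, Chain, Connection, Residue, StructureModel

from conftest import make_filament


def rigid_transform(model, seed=0):
    """Arbitrary rotation + translation of every atom (returns a copy)."""
    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    shift = rng.uniform(-50, 50, size=3)
    out = model.copy()
    for chain in out.chains:
        for res in chain.residues:
            for atom in res.atoms:
                atom.xyz = rot @ atom.xyz + shift
    return out


class TestIndexSubunits:
    def test_generation_order(self):
        model, _ = make_filament(seed=0, sigma=0.1, n_subunits=5)
        idx = index_subunits(model)
        assert idx.index == {"A": 0, "B": 1, "C": 2, "D": 3, "E": 4}

    def test_two_stacked_chains(self):
        model, _ = make_filament(seed=0, sigma=0.0, n_subunits=2)
        assert index_subunits(model).index == {"A": 0, "B": 1}

    def test_order_survives_rigid_motion(self):
        model, _ = make_filament(seed=1, sigma=0.1, n_subunits=5)
        moved = rigid_transform(model, seed=3)
        assert index_subunits(moved).index == index_subunits(model).index

    def test_single_chain_error(self):
        model, _ = make_filament(seed=0, sigma=0.0, n_subunits=1)
        with pytest.raises(ValueError):
            index_subunits(model)


class TestDetectDsc:
    def test_planted_offsets_recovered(self):
        """Tail contacts planted at offsets {1,2}: both called, fractions ≥ 0.9."""
        model, _ = make_filament(seed=2, sigma=0.1)
        report = detect_dsc(model)
        assert report.called_offsets() == [1, 2]
        interior = [r for r in report.per_chain if set(r.called) == {1, 2}]
        assert len(interior) >= 3
        for rep in interior:
            assert rep.fractions[1] + rep.fractions[2] >= 0.9
            assert rep.tail_range == (24, 33)

    def test_well_separated_chains_no_calls(self):
        model, _ = make_filament(
            seed=2, sigma=0.0, operator=HelicalOperator(-103.234, 200.0),
            tail_contacts=None, isopeptide=None,
        )
        report = detect_dsc(model)
        assert report.called_offsets() == []
        assert all(not r.fractions for r in report.per_chain)

    def test_fractions_invariant_under_rigid_motion(self):
        model, _ = make_filament(seed=4, sigma=0.1)
        moved = rigid_transform(model, seed=9)
        a = {r.chain_id: r.fractions for r in detect_dsc(model).per_chain}
        b = {r.chain_id: r.fractions for r in detect_dsc(moved).per_chain}
        for cid in a:
            assert set(a[cid]) == set(b[cid])
            for k in a[cid]:
                assert a[cid][k] == pytest.approx(b[cid][k], abs=1e-9)

    def test_fractions_sum_to_at_most_one(self):
        model, _ = make_filament(seed=5, sigma=0.2)
        for rep in detect_dsc(model).per_chain:
            assert sum(rep.fractions.values()) <= 1.0 + 1e-9
            assert all(f >= 0 for f in rep.fractions.values())

    def test_short_chain_skipped(self, caplog):
        model, _ = make_filament(seed=0, sigma=0.0, n_subunits=2)
        model.chains[0].residues = model.chains[0].residues[:5]
        with caplog.at_level(logging.WARNING, logger="threadarch"):
            report = detect_dsc(model)
        assert [r.chain_id for r in report.per_chain] == ["B"]


class TestDetectIsopeptide:
    def test_planted_bond_recovered(self):
        model, manifest = make_filament(seed=3, sigma=0.1)
        bonds = detect_isopeptide(model)
        assert len(bonds) == manifest["isopeptide"]["n_bonds"]
        for b in bonds:
            assert b.donor_position == 57 and b.donor_residue == "ASN"
            assert b.acceptor_position == 24 and b.offset == 2
            assert b.distance == pytest.approx(1.33, abs=0.01)
            assert b.planarity_deviation < 30.0

    def test_no_planted_bond_no_candidates(self):
        model, _ = make_filament(seed=3, sigma=0.1, isopeptide=None)
        assert detect_isopeptide(model) == []

    def test_planted_offset_three(self):
        model, _ = make_filament(seed=8, sigma=0.0, n_subunits=6, isopeptide=(57, 3))
        bonds = detect_isopeptide(model)
        assert len(bonds) == 3 and all(b.offset == 3 for b in bonds)

    def test_survey_mode_widens_cutoff(self):
        model, _ = make_filament(seed=3, sigma=0.0)
        # push the planted bonds just past the covalent cutoff
        for b in detect_isopeptide(model):
            pass
        strict = detect_isopeptide(model, bond_cutoff=1.0)
        survey = detect_isopeptide(model, bond_cutoff=1.0, survey=True)
        assert strict == [] and len(survey) == 4


class TestScanSequons:
    @pytest.mark.parametrize(
        "seq,expected",
        [("NAT", [1]), ("NPT", []), ("NNTT", [1, 2]), ("MNGSA", [2]), ("", [])],
    )
    def test_known_cases(self, seq, expected):
        assert [h.position for h in scan_sequons(seq)] == expected

    def test_numbering_offset(self, target_sequence):
        hits = scan_sequons(target_sequence, numbering_start=24)
        assert [h.position for h in hits] == [56, 80, 83, 121, 146]
        assert all(h.triplet[0] == "N" for h in hits)

    @settings(deadline=None, max_examples=200)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=0, max_size=40))
    def test_matches_pattern_oracle(self, seq):
        """Scanner agrees with a position-by-position triplet check."""
        expected = [
            i + 1
            for i in range(len(seq) - 2)
            if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in "ST"
        ]
        assert [h.position for h in scan_sequons(seq)] == expected

    def test_model_readout_matches_fasta_scan(self):
        model, _ = make_filament(seed=0, sigma=0.0, n_subunits=2)
        seq, start = chain_sequence(model.chains[0])
        assert start == 24
        hits = scan_sequons(seq, numbering_start=start, source="model")
        assert [h.position for h in hits] == [56, 80, 83, 121, 146]
        assert all(h.source == "model" for h in hits)


def glycan_fixture(n_sugars=6):
    """Asn56 → NAG → NAG branching to MAN, MAN, GLC, SQV (truncatable)."""

    def sugar(pos, name, x):
        return Residue(pos, name, [Atom("C1", "C", [float(x), 0.0, 0.0])], hetero=True)

    names = [(301, "NAG"), (302, "NAG"), (303, "MAN"), (304, "MAN"), (305, "GLC"), (306, "SQV")]
    keep = names[:n_sugars]
    residues = [Residue(56, "ASN", [Atom("ND2", "N", [0.0, 0.0, 0.0])])]
    residues += [sugar(p, n, 2 * i + 2) for i, (p, n) in enumerate(keep)]
    connections = [Connection("A", 56, "ND2", "A", 301, "C1")]
    if n_sugars >= 2:
        connections.append(Connection("A", 301, "C1", "A", 302, "C1"))
    for pos, _ in keep[2:]:
        connections.append(Connection("A", 302, "C1", "A", pos, "C1"))
    return StructureModel([Chain("A", residues)], connections)


class TestValidateGlycans:
    def test_two_sugar_core_incomplete(self):
        (tree,) = validate_glycans(glycan_fixture(2))
        assert tree.asn_position == 56 and tree.n_sugars == 2
        assert tree.counts == {"GlcNAc": 2}
        assert not tree.complete and tree.branch_position is None

    def test_full_hexasaccharide_complete(self):
        (tree,) = validate_glycans(glycan_fixture(6))
        assert tree.complete
        assert tree.counts == {"GlcNAc": 2, "Man": 2, "Glc": 1, "sulfoquinovose": 1}
        assert tree.branch_position == 302  # branch at the second GlcNAc

    def test_orphan_sugar_warns(self, caplog):
        model = glycan_fixture(2)
        model.connections = model.connections[1:]  # detach the tree from the Asn
        with caplog.at_level(logging.WARNING, logger="threadarch"):
            trees = validate_glycans(model)
        assert trees == []
        assert any("not attached" in rec.message for rec in caplog.records)

    def test_unglycosylated_asn_ignored(self):
        model = StructureModel(
            [Chain("A", [Residue(10, "ASN", [Atom("ND2", "N", [0, 0, 0])])])], []
        )
        assert validate_glycans(model) == []


class TestMeasureDiameter:
    def test_cylinder_of_known_radius(self):
        # rings of radius 20 Å about the z axis, one chain per height band
        theta = np.linspace(0.0, 2 * np.pi, 60, endpoint=False)
        chains = []
        for band in range(4):
            residues = []
            for level in range(5):
                z = band * 25.0 + level * 5.0
                for i, t in enumerate(theta):
                    residues.append(
                        Residue(
                            100 * level + i + 1, "ALA",
                            [Atom("CA", "C", [20 * np.cos(t), 20 * np.sin(t), z])],
                        )
                    )
            chains.append(Chain("ABCD"[band], residues))
        model = StructureModel(chains)
        assert measure_diameter(model) == pytest.approx(40.0, rel=0.005)

    def test_single_atom_on_axis(self):
        model = StructureModel([Chain("A", [Residue(1, "ALA", [Atom("CA", "C", [0, 0, 0])])])])
        assert measure_diameter(model) == 0.0

    def test_invariant_under_axial_motion(self):
        model, _ = make_filament(seed=6, sigma=0.1)
        d0 = measure_diameter(model)
        moved = model.copy()
        rot = Rotation.from_euler("z", 73.0, degrees=True).as_matrix()
        for chain in moved.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    atom.xyz = rot @ atom.xyz + np.array([0.0, 0.0, 17.0])
        assert measure_diameter(moved) == pytest.approx(d0, abs=1e-6)

    def test_atom_set_selection(self):
        model = glycan_fixture(6)
        assert measure_diameter(model, atom_set="all") > measure_diameter(model)

    def test_bad_atom_set(self):
        model, _ = make_filament(seed=0, sigma=0.0, n_subunits=2)
        with pytest.raises(ValueError):
            measure_diameter(model, atom_set="carbon")
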