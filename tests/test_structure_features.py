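"""Structural detectors: ASA, H-bonds, secondary structure, contacts, packing."""

import math

import numpy as np
import pytest

from mutexplain.bio_io import AtomRecord, Residue, Structure, read_pdb, write_pdb
from mutexplain.config import RunConfig
from mutexplain.structure_features import (
    assign_secondary_structure,
    compute_asa,
    compute_features,
    compute_rsa,
    detect_disulfides,
    detect_hbonds,
    detect_ligand_contacts,
    detect_salt_bridges,
    packing_density,
    to_feature_records,
)
from mutexplain.residue_mapping import map_sequences


def _atom(serial, name, resname, chain, num, x, y, z, element=None, het=False):
    return AtomRecord(
        serial=serial, name=name, altloc=" ", residue_name=resname, chain=chain,
        residue_number=num, insertion_code=" ", x=x, y=y, z=z,
        element=element or name[0], is_hetero=het,
    )


def _structure(atoms):
    residues = []
    index = {}
    chains = []
    for a in atoms:
        key = (a.chain, a.residue_number, a.insertion_code, a.is_hetero)
        if key not in index:
            r = Residue(chain=a.chain, number=a.residue_number,
                        insertion_code=a.insertion_code, name=a.residue_name,
                        is_hetero=a.is_hetero)
            index[key] = r
            residues.append(r)
            if a.chain not in chains:
                chains.append(a.chain)
        index[key].atoms.append(a)
    return Structure(atoms=atoms, chains=chains, residues=residues)


def _random_isometry(rng):
    m = rng.normal(size=(3, 3))
    q, _ = np.linalg.qr(m)
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-20, 20, size=3)
    return q, t


def _transform_structure(structure, rot, trans):
    atoms = []
    for a in structure.atoms:
        xyz = rot @ a.coord + trans
        atoms.append(_atom(a.serial, a.name, a.residue_name, a.chain,
                           a.residue_number, *xyz, element=a.element,
                           het=a.is_hetero))
    return _structure(atoms)


class TestAsa:
    def test_isolated_carbon_matches_closed_form(self):
        s = _structure([_atom(1, "C", "ALA", "A", 1, 0, 0, 0)])
        per_atom, per_res = compute_asa(s)
        expected = 4 * math.pi * (1.87 + 1.4) ** 2
        assert per_atom[1] == pytest.approx(expected, rel=0.01)
        assert per_res[("A", 1, " ")] == per_atom[1]

    def test_distant_atoms_do_not_occlude(self):
        s = _structure([
            _atom(1, "C", "ALA", "A", 1, 0, 0, 0),
            _atom(2, "C", "ALA", "A", 2, 100, 0, 0),
        ])
        per_atom, _ = compute_asa(s)
        expected = 4 * math.pi * (1.87 + 1.4) ** 2
        assert per_atom[1] == pytest.approx(expected, rel=0.01)
        assert per_atom[2] == pytest.approx(expected, rel=0.01)

    def test_fully_enclosed_residue_is_buried(self, clash_core):
        structure, manifest = clash_core
        _, per_res = compute_asa(structure)
        key = ("A", manifest["buried_residue"], " ")
        assert per_res[key] < manifest["max_asa"]

    def test_point_count_convergence(self, helix):
        """The 960-point lattice is within 2% of a denser 4000-point run."""
        structure, _ = helix
        _, coarse = compute_asa(structure, n_points=960)
        _, fine = compute_asa(structure, n_points=4000)
        for key, v_fine in fine.items():
            if v_fine > 1.0:
                assert abs(coarse[key] - v_fine) / v_fine < 0.02

    def test_neighbor_deletion_is_monotone(self, helix):
        """Removing any residue never decreases another atom's ASA."""
        structure, _ = helix
        per_atom, _ = compute_asa(structure)
        # delete the central residue entirely
        kept = [a for a in structure.atoms if a.residue_number != 6]
        reduced = _structure(kept)
        per_atom2, _ = compute_asa(reduced)
        for serial, asa in per_atom2.items():
            assert asa >= per_atom[serial] - 1e-9

    def test_rotation_translation_invariance(self, helix):
        structure, _ = helix
        rng = np.random.default_rng(42)
        rot, trans = _random_isometry(rng)
        moved = _transform_structure(structure, rot, trans)
        _, ref = compute_asa(structure)
        _, new = compute_asa(moved)
        for key in ref:
            # the lattice is not rotated with the molecule, so allow the
            # small sampling jitter of the point density
            assert new[key] == pytest.approx(ref[key], abs=2.0, rel=0.05)

    def test_zero_atoms_rejected(self):
        s = _structure([_atom(1, "C", "ALA", "A", 1, 0, 0, 0)])
        s.atoms = []
        with pytest.raises(ValueError):
            compute_asa(s)


class TestRsa:
    @pytest.mark.parametrize("asa,expected", [
        (0.0, "BURIED"),
        (100.5, "EXPOSED"),   # 100.5/201 = 0.5 for LEU
        (20.0, "PARTIALLY_BURIED"),
    ])
    def test_burial_classes(self, asa, expected):
        r = Residue(chain="A", number=1, insertion_code=" ", name="LEU")
        rsa = compute_rsa({("A", 1, " "): asa}, [r])
        assert rsa[("A", 1, " ")][1] == expected

    def test_unknown_residue_type(self):
        r = Residue(chain="A", number=1, insertion_code=" ", name="XYZ")
        rsa = compute_rsa({("A", 1, " "): 50.0}, [r])
        assert rsa[("A", 1, " ")] == (None, "UNKNOWN")

    def test_rsa_capped_for_extended_conformations(self):
        r = Residue(chain="A", number=1, insertion_code=" ", name="GLY")
        rsa = compute_rsa({("A", 1, " "): 500.0}, [r])
        assert rsa[("A", 1, " ")][0] == pytest.approx(1.2)


class TestHbondsAndSecondaryStructure:
    def test_helix_fixture_recovers_manifest_bonds(self, helix):
        structure, manifest = helix
        bonds, _ = detect_hbonds(structure)
        found = sorted((b.donor[1], b.acceptor[1]) for b in bonds)
        assert found == manifest["hbonds"]

    def test_helix_interior_assigned_h(self, helix):
        structure, manifest = helix
        bonds, _ = detect_hbonds(structure)
        ss = assign_secondary_structure(bonds, structure)
        for num in manifest["helix_residues"]:
            assert ss[("A", num, " ")] == "H"

    def test_extended_chain_has_no_bonds_and_all_coil(self, extended_chain):
        structure, manifest = extended_chain
        bonds, _ = detect_hbonds(structure)
        assert bonds == []
        ss = assign_secondary_structure(bonds, structure)
        assert "".join(ss[r.key] for r in structure.polymer_residues()) == manifest["ss"]

    def test_antiparallel_sheet_assigned_e(self, sheet):
        structure, manifest = sheet
        bonds, _ = detect_hbonds(structure)
        ss = assign_secondary_structure(bonds, structure)
        e_residues = sorted(
            (r.chain, r.number) for r in structure.polymer_residues()
            if ss[r.key] == "E"
        )
        assert e_residues == manifest["strand_residues"]

    def test_distant_residues_never_bond(self, helix):
        structure, _ = helix
        bonds, _ = detect_hbonds(structure)
        residues = structure.polymer_residues()
        ca = {r.key: r.atom("CA").coord for r in residues}
        for b in bonds:
            assert np.linalg.norm(ca[b.donor] - ca[b.acceptor]) < 20.0

    def test_all_accepted_bonds_below_cutoff(self, helix, sheet):
        cfg = RunConfig()
        for structure, _ in (helix, sheet):
            bonds, _ = detect_hbonds(structure)
            assert all(b.energy < cfg.hbond_energy_cutoff for b in bonds)

    def test_incomplete_backbone_skipped_with_warning(self, helix):
        structure, _ = helix
        atoms = [a for a in structure.atoms
                 if not (a.residue_number == 3 and a.name == "O")]
        s = _structure(atoms)
        _, warnings = detect_hbonds(s)
        assert any("A3" in w for w in warnings)


class TestContacts:
    def test_disulfide_fixture_pair(self, disulfide_site):
        structure, manifest = disulfide_site
        pairs = detect_disulfides(structure)
        assert len(pairs) == 1
        (k1, k2, d) = pairs[0]
        assert (k1[1], k2[1]) == manifest["disulfides"][0]
        assert d == pytest.approx(manifest["sg_distance"], abs=1e-3)

    def test_distant_cysteines_not_paired(self):
        s = _structure([
            _atom(1, "SG", "CYS", "A", 1, 0, 0, 0, element="S"),
            _atom(2, "SG", "CYS", "A", 4, 5, 0, 0, element="S"),
        ])
        assert detect_disulfides(s) == []

    def test_closest_cysteine_wins(self):
        s = _structure([
            _atom(1, "SG", "CYS", "A", 1, 0, 0, 0, element="S"),
            _atom(2, "SG", "CYS", "A", 4, 2.0, 0, 0, element="S"),
            _atom(3, "SG", "CYS", "A", 8, -2.4, 0, 0, element="S"),
        ])
        pairs = detect_disulfides(s)
        assert len(pairs) == 1
        assert {pairs[0][0][1], pairs[0][1][1]} == {1, 4}

    def test_salt_bridge_fixture(self, salt_bridge_site):
        structure, manifest = salt_bridge_site
        bridges = detect_salt_bridges(structure)
        assert len(bridges) == 1
        ka, kb, d = bridges[0]
        assert {ka[1], kb[1]} == set(manifest["salt_bridges"][0])
        assert d == pytest.approx(manifest["distance"], abs=1e-3)

    def test_salt_bridge_beyond_cutoff_ignored(self):
        s = _structure([
            _atom(1, "NZ", "LYS", "A", 1, 0, 0, 0, element="N"),
            _atom(2, "OE1", "GLU", "A", 4, 6.0, 0, 0, element="O"),
        ])
        assert detect_salt_bridges(s) == []

    def test_metal_contact_fixture(self, metal_site):
        structure, manifest = metal_site
        contacts = detect_ligand_contacts(structure)
        (resnum, het) = manifest["ligand_contacts"][0]
        lst = contacts[("A", resnum, " ")]
        assert lst[0][0] == het
        assert lst[0][1] == pytest.approx(manifest["distance"], abs=1e-3)
        assert lst[0][2] is True  # flagged as ion

    def test_water_not_a_ligand(self):
        s = _structure([
            _atom(1, "CA", "ALA", "A", 1, 0, 0, 0),
            _atom(2, "O", "HOH", "W", 1, 2.8, 0, 0, het=True),
        ])
        assert detect_ligand_contacts(s) == {}

    def test_detectors_invariant_under_isometry(self, disulfide_site,
                                                salt_bridge_site, metal_site):
        rng = np.random.default_rng(3)
        for structure, _ in (disulfide_site, salt_bridge_site, metal_site):
            rot, trans = _random_isometry(rng)
            moved = _transform_structure(structure, rot, trans)
            assert len(detect_disulfides(moved)) == len(detect_disulfides(structure))
            assert len(detect_salt_bridges(moved)) == len(detect_salt_bridges(structure))
            assert len(detect_ligand_contacts(moved)) == len(
                detect_ligand_contacts(structure))


class TestPacking:
    def test_clash_core_center_is_densely_packed(self, clash_core):
        structure, manifest = clash_core
        count = packing_density(structure, ("A", manifest["buried_residue"], " "))
        assert count >= manifest["min_neighbor_count"]

    def test_isolated_residue_has_no_neighbors(self):
        s = _structure([
            _atom(1, "CA", "GLY", "A", 1, 0, 0, 0),
            _atom(2, "CA", "GLY", "A", 2, 50, 0, 0),
        ])
        assert packing_density(s, ("A", 1, " ")) == 0

    def test_count_invariant_under_rotation(self, clash_core):
        structure, manifest = clash_core
        key = ("A", manifest["buried_residue"], " ")
        rng = np.random.default_rng(5)
        rot, trans = _random_isometry(rng)
        moved = _transform_structure(structure, rot, trans)
        assert packing_density(moved, key) == packing_density(structure, key)


class TestFeatureExport:
    def test_disulfide_records_mutually_partnered(self, disulfide_site):
        structure, _ = disulfide_site
        features = compute_features(structure)
        seq = structure.sequence()
        mapping = map_sequences(seq, seq)
        records, _ = to_feature_records(features, structure, mapping, "P1")
        ds = [r for r in records if r.feature_type == "DISULFID"]
        assert len(ds) == 2
        assert {(r.begin, int(r.partner)) for r in ds} == {(1, 2), (2, 1)}

    def test_helix_run_is_run_length_encoded(self, helix):
        structure, manifest = helix
        features = compute_features(structure)
        seq = structure.sequence()
        mapping = map_sequences(seq, seq)
        records, _ = to_feature_records(features, structure, mapping, "P1")
        ss = [r for r in records if r.feature_type == "SECONDARY_STRUCTURE"]
        assert len(ss) == 1
        assert (ss[0].begin, ss[0].end) == (
            manifest["helix_residues"][0], manifest["helix_residues"][-1])
        assert "helix" in ss[0].description

    def test_unmapped_residue_dropped_with_warning(self, helix):
        structure, _ = helix
        features = compute_features(structure)
        # submitted sequence misses the first two residues of the structure
        mapping = map_sequences(structure.sequence(), structure.sequence()[2:])
        records, warnings = to_feature_records(features, structure, mapping, "P1")
        assert all(r.begin >= 1 for r in records)
        assert any("not mappable" in w for w in warnings)

    def test_all_records_are_structure_tier(self, metal_site):
        structure, _ = metal_site
        features = compute_features(structure)
        seq = structure.sequence()
        mapping = map_sequences(seq, seq)
        records, _ = to_feature_records(features, structure, mapping, "P1")
        assert records and all(r.source_tier == "STRUCTURE" for r in records)
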