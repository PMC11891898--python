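"""Structure parsing, termini, masses, area files and per-type accumulation."""

import numpy as np
import pytest

import ride
from ride.structure_io import (CAP_KEY, AtomAreaTable, Structure,
                               StructureError, accumulate_sesa_by_restype,
                               detect_termini, molecular_weight,
                               read_area_file, read_pdb, write_area_file,
                               write_pdb)

ALA_FRAGMENT = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.685   7.042  -4.963  1.00  0.00           C
ATOM      4  O   ALA A   1      13.405   7.376  -5.910  1.00  0.00           O
ATOM      5  CB  ALA A   1      10.497   6.313  -4.163  1.00  0.00           C
END
"""


def test_read_pdb_identity_parse(tmp_path):
    """A hand-written 5-atom ALA fragment parses atom-for-atom, in A->nm."""
    path = tmp_path / "ala.pdb"
    path.write_text(ALA_FRAGMENT)
    s = read_pdb(path)
    assert s.n_atoms == 5
    assert len(s.residues) == 1 and s.residues[0].name == "ALA"
    assert s.sequence == "A"
    np.testing.assert_allclose(s.atoms[0].position,
                               [1.1104, 0.6134, -0.6504], atol=1e-6)


def test_read_pdb_caps_flagged_and_excluded_from_sequence(tmp_path):
    s = ride.build_peptide(ride.PeptideSpec("A", "extended", capped=True))
    path = tmp_path / "capped.pdb"
    write_pdb(s, path)
    back = read_pdb(path)
    assert [r.name for r in back.residues] == ["ACE", "ALA", "NME"]
    assert back.sequence == "A"
    assert back.residues[0].is_cap and back.residues[2].is_cap


def test_pdb_round_trip_coordinates(tmp_path):
    """write_pdb then read_pdb preserves decapeptide coordinates to 1e-3 nm
    (PDB format precision is 1e-4 nm)."""
    s = ride.build_peptide(ride.PeptideSpec("A" * 10, "extended",
                                            capped=True))
    path = tmp_path / "deca.pdb"
    write_pdb(s, path)
    back = read_pdb(path)
    assert back.n_atoms == s.n_atoms
    np.testing.assert_allclose(back.coordinates(), s.coordinates(),
                               atol=1e-3)


def test_read_pdb_errors(tmp_path):
    empty = tmp_path / "empty.pdb"
    empty.write_text("END\n")
    with pytest.raises(StructureError):
        read_pdb(empty)
    unknown = tmp_path / "unk.pdb"
    unknown.write_text(ALA_FRAGMENT.replace("ALA", "XYZ"))
    with pytest.raises(StructureError, match="XYZ"):
        read_pdb(unknown)


class TestDetectTermini:
    def test_capped(self):
        s = ride.build_peptide(ride.PeptideSpec("A", capped=True))
        assert detect_termini(s) == "capped"

    def test_bare_chain_is_zwitterionic(self):
        s = ride.build_peptide(ride.PeptideSpec("GAVLK" * 4, capped=False))
        assert detect_termini(s) == "zwitterionic"

    def test_single_cap_conservative_default_with_warning(self):
        s = ride.build_peptide(ride.PeptideSpec("A", capped=True))
        atoms = [a for a in s.atoms if a.residue_name != "NME"]
        partial = Structure(atoms)
        with pytest.warns(UserWarning, match="one terminal cap"):
            assert detect_termini(partial) == "zwitterionic"

    def test_invariant_to_atom_order_within_residues(self):
        s = ride.build_peptide(ride.PeptideSpec("AG", capped=True))
        atoms = []
        for res in s.residues:
            lo, hi = res.atom_span
            atoms.extend(reversed(s.atoms[lo:hi]))
        assert detect_termini(Structure(atoms)) == detect_termini(s)


class TestAreaFiles:
    def test_unit_conversion(self, tmp_path):
        s = ride.gen_sphere_cluster(2, 0.15, 1.0)
        f = tmp_path / "areas.txt"
        f.write_text("1 10.0\n2 20.0\n")
        table = read_area_file(f, s)
        assert table.areas == {1: pytest.approx(0.10), 2: pytest.approx(0.20)}
        assert table.source == "external_file"

    def test_header_skipped(self, tmp_path):
        s = ride.gen_sphere_cluster(2, 0.15, 1.0)
        f = tmp_path / "areas.txt"
        f.write_text("# msms areas\natom area\n1 10.0\n2 20.0\n")
        assert read_area_file(f, s).areas[2] == pytest.approx(0.20)

    def test_count_mismatch_names_both_counts(self, tmp_path):
        s = ride.gen_sphere_cluster(3, 0.15, 1.0)
        f = tmp_path / "areas.txt"
        f.write_text("1 10.0\n2 20.0\n")
        with pytest.raises(StructureError, match="2.*3"):
            read_area_file(f, s)

    def test_negative_area_rejected(self, tmp_path):
        s = ride.gen_sphere_cluster(1, 0.15, 1.0)
        f = tmp_path / "areas.txt"
        f.write_text("1 -1.0\n")
        with pytest.raises(StructureError, match="negative"):
            read_area_file(f, s)

    def test_internal_export_round_trip(self, tmp_path):
        """compute_sesa output exported then re-read is identical."""
        s = ride.gen_sphere_cluster(2, 0.15, 0.25)
        ride.assign_radii(s)
        table = ride.compute_sesa(s).as_area_table()
        f = tmp_path / "areas.txt"
        write_area_file(table, s, f)
        back = read_area_file(f, s)
        for serial in table.areas:
            assert back.areas[serial] == pytest.approx(table.areas[serial],
                                                       abs=1e-7)


class TestMolecularWeight:
    def test_zwitterionic_tripeptide(self):
        s = ride.build_peptide(ride.PeptideSpec("AAA", capped=False))
        assert molecular_weight(s) * 1000 == pytest.approx(231.25, abs=0.01)

    def test_glycine_monomer(self):
        s = ride.build_peptide(ride.PeptideSpec("G", capped=False))
        assert molecular_weight(s) * 1000 == pytest.approx(75.07, abs=0.01)

    def test_capped_includes_cap_masses_not_water(self):
        s = ride.build_peptide(ride.PeptideSpec("A", capped=True))
        # ALA residue + ACE + NME
        assert molecular_weight(s) * 1000 == pytest.approx(
            71.0788 + 43.0446 + 30.0499, abs=0.01)

    def test_empty_structure_errors(self):
        with pytest.raises(StructureError):
            molecular_weight(Structure([]))

    def test_unknown_residue_named_in_error(self):
        s = ride.gen_sphere_cluster(1, 0.15, 1.0)
        with pytest.raises(StructureError, match="SPH"):
            molecular_weight(s)


class TestAccumulate:
    def test_additivity_two_ala(self):
        s = ride.build_peptide(ride.PeptideSpec("AA", capped=False))
        n = s.n_atoms
        per_res = {}
        for res in s.residues:
            lo, hi = res.atom_span
            for a in s.atoms[lo:hi]:
                per_res[a.serial] = 0.3 / (hi - lo) if res.index == 1 \
                    else 0.4 / (hi - lo)
        table = AtomAreaTable(per_res)
        acc = accumulate_sesa_by_restype(s, table)
        assert acc["ALA"] == pytest.approx(0.7)
        assert sum(acc.values()) == pytest.approx(table.total)

    def test_zero_table_gives_all_zeros(self):
        s = ride.build_peptide(ride.PeptideSpec("AG", capped=True))
        table = AtomAreaTable({a.serial: 0.0 for a in s.atoms})
        acc = accumulate_sesa_by_restype(s, table)
        assert all(v == 0.0 for v in acc.values())
        assert set(acc) == set(ride.constants.STANDARD_AAS) | {CAP_KEY}

    def test_matches_brute_force_grouping_and_conserves_total(self):
        """Mixed ALA/GLY fixture vs a per-atom brute-force sum; the per-type
        map (+ CAP) conserves the per-atom total to 1e-9 nm^2."""
        s = ride.build_peptide(ride.PeptideSpec("AGAG", capped=True))
        rng = np.random.default_rng(7)
        table = AtomAreaTable({a.serial: float(rng.uniform(0, 0.1))
                               for a in s.atoms})
        acc = accumulate_sesa_by_restype(s, table)
        brute = {}
        res_of = s.residue_of_atom()
        for i, a in enumerate(s.atoms):
            res = s.residues[res_of[i]]
            key = CAP_KEY if res.name in ("ACE", "NME") else res.name
            brute[key] = brute.get(key, 0.0) + table.areas[a.serial]
        for key, val in brute.items():
            assert acc[key] == pytest.approx(val, abs=1e-12)
        assert sum(acc.values()) == pytest.approx(table.total, abs=1e-9)
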