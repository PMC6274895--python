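"""Structure I/O: PDB round trips, bias-atom selection, dihedrals, filters."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pmfrich import fixture_gen, structure_io as sio

finite = st.floats(-10, 10, allow_nan=False)
point = st.tuples(finite, finite, finite).map(np.array)


def _write(tmp_path, text, name="x.pdb"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadWrite:
    def test_minimal_one_atom_angstrom_to_nm(self, tmp_path):
        p = _write(tmp_path,
                   "ATOM      1  CA  ALA A   1      11.000  22.000 -33.000"
                   "  1.00  0.00           C\nEND\n")
        rec = sio.read_structure(p)
        assert rec.n_atoms == 1
        np.testing.assert_allclose(rec.atoms[0].position,
                                   [1.1, 2.2, -3.3], atol=1e-12)

    def test_round_trip_preserves_names_indices_coords(self, tmp_path):
        rec = fixture_gen.build_polypeptide([0, -57, -60, -70, 0],
                                            [-47, -40, -30, 0, 0])
        path = tmp_path / "chain.pdb"
        sio.write_structure(rec, path)
        back = sio.read_structure(path)
        assert back.n_atoms == rec.n_atoms
        pos2 = {(a.chain_id, a.res_index, a.name): a.position for a in back.atoms}
        for a in rec.atoms:
            key = (a.chain_id, a.res_index, a.name)
            assert key in pos2
            # PDB stores 3 decimals in Å = 1e-4 nm resolution
            np.testing.assert_allclose(pos2[key], a.position, atol=5.1e-5)

    def test_water_only_file_flagged_as_polymer_empty(self, tmp_path):
        p = _write(tmp_path,
                   "HETATM    1  O   HOH A   1       1.000   1.000   1.000"
                   "  1.00  0.00           O\nEND\n")
        rec = sio.read_structure(p)
        assert rec.metadata.get("polymer_empty") is True

    def test_unparsable_and_missing_files_raise(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            sio.read_structure(tmp_path / "absent.pdb")
        p = _write(tmp_path, "")
        with pytest.raises(sio.EmptyStructureError):
            sio.read_structure(p)

    def test_record_invariants_enforced(self):
        a = sio.Atom("CA", "C", "ALA", 1, "A", np.zeros(3))
        b = sio.Atom("CA", "C", "ALA", 1, "A", np.ones(3))
        with pytest.raises(ValueError, match="duplicate"):
            sio.StructureRecord(atoms=[a, b])


class TestBiasAtomSelection:
    def test_protein_backbone_four_atoms_per_residue(self):
        rec = fixture_gen.build_polypeptide([0, -57], [-47, 0])
        idx = sio.select_bias_atoms(rec, "protein")
        assert [rec.atoms[i].name for i in idx] == ["N", "CA", "C", "O"] * 2

    def test_guanine_nucleotide_selection(self):
        rec = fixture_gen.build_dna_dinucleotide({}, {}, res_names=("DG", "DC"))
        idx = sio.select_bias_atoms(rec, "dna")
        names = [rec.atoms[i].name for i in idx]
        assert names[:6] == ["P", "O5'", "C5'", "C4'", "N9", "C4"]
        assert names[6:] == ["P", "O5'", "C5'", "C4'", "N1", "C2"]

    def test_five_prime_terminal_without_p_gives_five_atoms(self):
        rec = fixture_gen.build_dna_dinucleotide({}, {})
        atoms = [a for a in rec.atoms if not (a.res_index == 1 and a.name == "P")]
        rec2 = sio.StructureRecord(atoms=atoms, sequences=rec.sequences)
        idx = sio.select_bias_atoms(rec2, "dna")
        res1 = [rec2.atoms[i].name for i in idx
                if rec2.atoms[i].res_index == 1]
        assert len(res1) == 5 and "P" not in res1

    def test_empty_record_gives_empty_list(self):
        assert sio.select_bias_atoms(sio.StructureRecord(), "protein") == []


class TestDihedral:
    def test_planar_cis_and_trans(self):
        p1, p2, p3 = np.array([1.0, 1, 0]), np.array([0.0, 0, 0]), np.array([1.0, 0, 0])
        cis = np.array([2.0, 1, 0])
        trans = np.array([2.0, -1, 0])
        assert sio.compute_dihedral(p1, p2, p3, cis) == pytest.approx(0.0, abs=1e-12)
        assert sio.compute_dihedral(p1, p2, p3, trans) == pytest.approx(180.0, abs=1e-9)

    def test_matches_independent_library_oracle(self, rng):
        from MDAnalysis.lib.distances import calc_dihedrals

        for _ in range(200):
            pts = rng.normal(size=(4, 3))
            want = math.degrees(float(calc_dihedrals(
                pts[0][None], pts[1][None], pts[2][None], pts[3][None])[0]))
            got = sio.compute_dihedral(*pts)
            # the reference library computes in single precision
            assert abs((got - want + 180) % 360 - 180) < 1e-4

    @settings(max_examples=100, derandomize=True)
    @given(p1=point, p2=point, p3=point, p4=point)
    def test_reversal_invariance_and_mirror_antisymmetry(self, p1, p2, p3, p4):
        """The signed dihedral is invariant under reversing the atom order
        and flips sign under mirror reflection."""
        try:
            fwd = sio.compute_dihedral(p1, p2, p3, p4)
        except sio.UndefinedTorsionError:
            return
        rev = sio.compute_dihedral(p4, p3, p2, p1)
        assert fwd == pytest.approx(rev, abs=1e-7)
        mirror = [p * np.array([1.0, 1.0, -1.0]) for p in (p1, p2, p3, p4)]
        ref = sio.compute_dihedral(*mirror)
        if abs(abs(fwd) - 180.0) > 1e-6:    # ±180 is the same angle
            assert ref == pytest.approx(-fwd, abs=1e-7)

    def test_collinear_raises(self):
        z = np.zeros(3)
        with pytest.raises(sio.UndefinedTorsionError):
            sio.compute_dihedral(z, [1, 0, 0], [2, 0, 0], [3, 1, 0])


class TestTorsionSeries:
    def test_ideal_helix_recovers_construction_angles(self):
        rec = fixture_gen.build_polypeptide([-57.0] * 6, [-47.0] * 6)
        df = sio.extract_torsion_series(rec, sio.PROTEIN_TORSIONS)
        phi = df[df.torsion == "phi"]["angle_deg"]
        psi = df[df.torsion == "psi"]["angle_deg"]
        assert len(phi) == 5 and len(psi) == 5
        np.testing.assert_allclose(phi, -57.0, atol=0.5)
        np.testing.assert_allclose(psi, -47.0, atol=0.5)

    def test_single_residue_has_no_phi_psi(self):
        rec = fixture_gen.build_polypeptide([0.0], [0.0])
        df = sio.extract_torsion_series(rec, sio.PROTEIN_TORSIONS)
        assert df.empty and df.attrs["n_omitted"] == 2

    def test_dna_dinucleotide_step_torsions(self):
        t1 = {"beta": -65.0, "gamma": 55.0, "delta": 130.0, "epsilon": -170.0,
              "zeta": -95.0, "chi": -110.0}
        t2 = {"alpha": -62.0, "beta": 175.0, "gamma": 48.0, "delta": 125.0,
              "chi": -105.0}
        rec = fixture_gen.build_dna_dinucleotide(t1, t2)
        df = sio.extract_torsion_series(rec, sio.DNA_TORSIONS)
        got = {(r.residue, r.torsion): r.angle_deg for r in df.itertuples()}
        for name, val in t1.items():
            assert got[(1, name)] == pytest.approx(val, abs=1e-6)
        for name, val in t2.items():
            assert got[(2, name)] == pytest.approx(val, abs=1e-6)
        # eight distinct backbone/glycosidic torsion names resolvable per step
        assert df[df.torsion == "alpha"].residue.tolist() == [2]


class TestDatasetFilter:
    @staticmethod
    def entry(**kw):
        base = dict(structure_id="x", resolution=2.0, polymer_type="protein",
                    chain_length=100, cluster=None, contains_rna=False,
                    contains_dna=False, protein_length=100)
        base.update(kw)
        return sio.DatasetEntry(**base)

    def test_protein_rules(self):
        keep = self.entry(resolution=2.4, chain_length=60)
        too_coarse = self.entry(resolution=2.6)
        too_short = self.entry(chain_length=50)
        has_dna = self.entry(contains_dna=True)
        out = sio.filter_dataset([keep, too_coarse, too_short, has_dna],
                                 "protein")
        assert out == [keep]

    def test_dna_rules(self):
        keep = self.entry(resolution=2.9, contains_dna=True, chain_length=12,
                          polymer_type="dna", protein_length=0)
        with_protein = self.entry(resolution=2.0, contains_dna=True,
                                  chain_length=12, protein_length=30)
        short_protein = self.entry(resolution=2.0, contains_dna=True,
                                   chain_length=12, protein_length=15)
        short_dna = self.entry(resolution=2.0, contains_dna=True, chain_length=5)
        has_rna = self.entry(resolution=2.0, contains_dna=True, chain_length=12,
                             contains_rna=True)
        out = sio.filter_dataset(
            [keep, with_protein, short_protein, short_dna, has_rna], "dna")
        assert out == [keep, with_protein]

    def test_cluster_keeps_best_resolution(self):
        a = self.entry(structure_id="a", resolution=2.4, cluster="c1")
        b = self.entry(structure_id="b", resolution=1.8, cluster="c1")
        c = self.entry(structure_id="c", resolution=2.0, cluster="c2")
        assert sio.filter_dataset([a, b, c], "protein") == [b, c]

    def test_missing_resolution_rejected(self):
        assert sio.filter_dataset([self.entry(resolution=None)], "protein") == []

    def test_idempotent(self):
        entries = [self.entry(structure_id=str(i), resolution=1.5 + 0.2 * i,
                              cluster="c" if i % 2 else None)
                   for i in range(8)]
        once = sio.filter_dataset(entries, "protein")
        assert sio.filter_dataset(once, "protein") == once

    def test_empty_list(self):
        assert sio.filter_dataset([], "dna") == []

    def test_read_dataset_table(self, tmp_path):
        p = tmp_path / "meta.tsv"
        p.write_text(
            "structure_id\tresolution\tpolymer_type\tchain_length\tcluster"
            "\tcontains_rna\tcontains_dna\tprotein_length\n"
            "1abc\t1.8\tprotein\t120\tc1\tFalse\tFalse\t120\n"
            "2xyz\t\tdna\t12\t\tFalse\tTrue\t0\n")
        entries = sio.read_dataset_table(p)
        assert entries[0].resolution == 1.8 and entries[0].cluster == "c1"
        assert entries[1].resolution is None and entries[1].contains_dna


class TestMultiModel:
    def test_trajectory_round_trip(self, tmp_path):
        recs = [fixture_gen.build_polypeptide([0, -57 - 10 * i], [-47, 0])
                for i in range(3)]
        path = tmp_path / "traj.pdb"
        sio.write_multi_model(recs, path)
        middle = sio.read_structure(path, model_index=1)
        assert middle.n_atoms == recs[1].n_atoms
        pos = {(a.res_index, a.name): a.position for a in middle.atoms}
        for a in recs[1].atoms:
            np.testing.assert_allclose(pos[(a.res_index, a.name)], a.position,
                                       atol=5.1e-5)
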