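import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spinlabel as sl
from spinlabel.fixtures import GXG_SITE
from conftest import brute_force_radius

GLY_PDB = """\
ATOM      1  N   GLY A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  GLY A   1       9.967   6.935  -6.697  1.00  0.00           C
ATOM      3  C   GLY A   1       9.000   6.500  -5.600  1.00  0.00           C
ATOM      4  O   GLY A   1       8.500   5.500  -5.700  1.00  0.00           O
END
"""


class TestReadPdb:
    def test_minimal_glycine(self):
        s = sl.read_pdb(GLY_PDB)
        assert len(s) == 4
        assert {a.name for a in s.atoms} == {"N", "CA", "C", "O"}
        np.testing.assert_allclose(s.atoms[0].position, [11.104, 6.134, -6.504])

    def test_malformed_coordinate_names_line(self):
        bad = GLY_PDB.replace("9.967", "9.9x7")
        with pytest.raises(sl.PDBParseError, match="line 2"):
            sl.read_pdb(bad)

    def test_empty_input_rejected(self):
        with pytest.raises(sl.PDBParseError):
            sl.read_pdb("END\n")

    def test_altloc_highest_occupancy_tie_prefers_a(self):
        two_alt = (
            "ATOM      1  N  BGLY A   1       1.000   0.000   0.000  0.50  0.00           N\n"
            "ATOM      2  N  AGLY A   1       2.000   0.000   0.000  0.50  0.00           N\n"
            "ATOM      3  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        s = sl.read_pdb(two_alt)
        n = [a for a in s.atoms if a.name == "N"]
        assert len(n) == 1
        assert n[0].position[0] == pytest.approx(2.0)  # altloc A wins the tie

    def test_hydrogen_flagging(self):
        with_h = GLY_PDB.replace(
            "END",
            "ATOM      5  H   GLY A   1       8.000   5.000  -5.000  1.00  0.00           H\nEND",
        )
        s = sl.read_pdb(with_h)
        assert [a.is_hydrogen for a in s.atoms] == [False] * 4 + [True]


class TestRoundTrip:
    def test_write_read_coordinates(self, gxg, tmp_path):
        path = tmp_path / "gxg.pdb"
        sl.write_pdb(gxg, path)
        back = sl.read_pdb(path)
        assert len(back) == len(gxg)
        np.testing.assert_allclose(back.coordinates(), gxg.coordinates(), atol=1e-3)

    def test_all_fixture_kinds_survive_round_trip(self, tmp_path):
        makers = [
            sl.fixtures.make_gxg_peptide,
            lambda: sl.fixtures.make_cone_pocket(90.0),
            lambda: sl.fixtures.make_wall(10.0),
            lambda: sl.fixtures.make_cage(2.5),
            lambda: sl.fixtures.make_symmetric_dimer(180.0),
        ]
        for i, make in enumerate(makers):
            s = make()
            path = tmp_path / f"f{i}.pdb"
            sl.write_pdb(s, path)
            back = sl.read_pdb(path)
            assert len(back) == len(s)
            np.testing.assert_allclose(back.coordinates(), s.coordinates(), atol=1e-3)


class TestSelectResidue:
    def test_middle_residue_only(self, gxg):
        atoms = sl.select_residue(gxg, GXG_SITE)
        assert {a.residue_number for a in atoms} == {2}
        assert {a.name for a in atoms} == {"N", "CA", "C", "O", "CB"}

    def test_nonexistent_chain_errors(self, gxg):
        with pytest.raises(sl.SiteError, match="not found"):
            sl.select_residue(gxg, sl.SiteRef("Z", 2))

    def test_insertion_code_selects_inserted_residue(self):
        text = (
            "ATOM      1  CA  GLY A  10       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  ALA A  10A      5.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  CB  ALA A  10A      5.500   1.000   0.000  1.00  0.00           C\n"
            "ATOM      4  CA  GLY A  11      10.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        s = sl.read_pdb(text)
        inserted = sl.select_residue(s, sl.SiteRef("A", 10, "A"))
        assert len(inserted) == 2
        assert {a.residue_name for a in inserted} == {"ALA"}
        plain = sl.select_residue(s, sl.SiteRef("A", 10))
        assert len(plain) == 1


class TestEnvironment:
    def test_excludes_labeled_residue(self, gxg):
        env = sl.environment_for_site(gxg, GXG_SITE)
        assert {a.residue_number for a in env} == {1, 3}

    def test_water_excluded_by_default(self, gxg, tmp_path):
        path = tmp_path / "with_water.pdb"
        sl.write_pdb(gxg, path)
        text = path.read_text().replace(
            "END",
            "HETATM   99  O   HOH A  50       3.000   3.000   3.000  1.00  0.00           O\nEND",
        )
        s = sl.read_pdb(text)
        env = sl.environment_for_site(s, GXG_SITE)
        assert all(a.residue_name != "HOH" for a in env)
        env_w = sl.environment_for_site(s, GXG_SITE, include_waters=True)
        assert any(a.residue_name == "HOH" for a in env_w)

    def test_counted_partition(self, gxg):
        """Environment size = heavy atoms - labeled residue - excluded het/water."""
        env = sl.environment_for_site(gxg, GXG_SITE)
        site_atoms = sl.select_residue(gxg, GXG_SITE)
        heavy = [a for a in gxg.atoms if not a.is_hydrogen]
        assert len(env) == len(heavy) - len(site_atoms)


class TestSpatialIndex:
    def test_empty_index(self):
        idx = sl.build_spatial_index([], cell_size=5.0)
        assert idx.query_radius(np.zeros(3), 4.5) == []

    def test_boundary_is_closed_ball(self):
        a = sl.Atom(name="C", element="C", position=np.array([3.39, 0, 0]),
                    residue_number=1, insertion_code="", chain_id="A", residue_name="PSD")
        b = sl.Atom(name="C", element="C", position=np.array([3.41, 0, 0]),
                    residue_number=2, insertion_code="", chain_id="A", residue_name="PSD")
        idx = sl.build_spatial_index([a, b], cell_size=2.0)
        hits = idx.query_radius(np.zeros(3), 3.4)
        assert [h.residue_number for h in hits] == [1]
        # an atom exactly at r is included
        c = sl.Atom(name="C", element="C", position=np.array([3.4, 0, 0]),
                    residue_number=3, insertion_code="", chain_id="A", residue_name="PSD")
        idx = sl.build_spatial_index([c], cell_size=2.0)
        assert len(idx.query_radius(np.zeros(3), 3.4)) == 1

    def test_matches_brute_force_on_random_queries(self, random_atoms):
        idx = sl.build_spatial_index(random_atoms, cell_size=5.0)
        rng = np.random.default_rng(7)
        for _ in range(100):
            point = rng.uniform(-5.0, 55.0, 3)
            got = {a.residue_number for a in idx.query_radius(point, 4.5)}
            assert got == brute_force_radius(random_atoms, point, 4.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        cell=st.floats(0.5, 10.0),
        r=st.floats(0.5, 15.0),
    )
    def test_equivalence_property(self, seed, cell, r):
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 60)
        coords = rng.uniform(-20, 20, size=(n, 3))
        atoms = [
            sl.Atom(name="C", element="C", position=p, residue_number=i,
                    insertion_code="", chain_id="X", residue_name="PSD")
            for i, p in enumerate(coords)
        ]
        idx = sl.build_spatial_index(atoms, cell_size=cell)
        point = rng.uniform(-25, 25, 3)
        got = {a.residue_number for a in sl.query_radius(idx, point, r)}
        assert got == brute_force_radius(atoms, point, r)


class TestEnsembleIO:
    def test_multi_model_blocks_and_round_trip(self, gxg, tmp_path):
        ens = sl.run_search(gxg, GXG_SITE, sl.SearchParams(thoroughness="quick", seed=7))
        assert len(ens) >= 1
        ens.conformers[0].snuggly = True
        path = tmp_path / "ens.pdb"
        sl.write_ensemble_pdb(ens, path)
        text = path.read_text()
        model_lines = [l for l in text.splitlines() if l.startswith("MODEL ")]
        assert len(model_lines) == len(ens)
        assert text.count("ENDMDL") == len(ens)
        assert "SNUGGLY MODEL    1 TRUE" in text
        back = sl.read_ensemble_pdb(path)
        assert len(back) == len(ens)
        assert back.conformers[0].snuggly is True
        for orig, re_read in zip(ens.conformers, back.conformers):
            np.testing.assert_allclose(
                re_read.coordinates, orig.coordinates, atol=1.5e-3
            )

    def test_empty_ensemble_rejected(self, gxg, tmp_path):
        cage = sl.fixtures.make_cage(2.5)
        ens = sl.run_search(cage, GXG_SITE, sl.SearchParams(thoroughness="quick", seed=0))
        assert len(ens) == 0
        with pytest.raises(ValueError):
            sl.write_ensemble_pdb(ens, tmp_path / "nope.pdb")
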