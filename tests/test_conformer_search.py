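import numpy as np
import pytest

import spinlabel as sl
from spinlabel.conformer_search import clash_count, internal_clash
from spinlabel.fixtures import GXG_SITE
from spinlabel.structure_io import SpatialIndex, environment_for_site


def pseudo(pos, num=1):
    return sl.Atom(name="C", element="C", position=np.asarray(pos, dtype=float),
                   residue_number=num, insertion_code="", chain_id="X",
                   residue_name="PSD")


class TestSearchParams:
    def test_thoroughness_presets(self):
        assert sl.THOROUGHNESS_TRIALS == {
            "painstaking": 1500, "thorough": 300, "normal": 90, "quick": 10,
        }
        for name, n in sl.THOROUGHNESS_TRIALS.items():
            assert sl.SearchParams(thoroughness=name).n_trials == n

    def test_vdw_range_enforced_unless_forced(self):
        with pytest.raises(ValueError, match="vdw_cutoff"):
            sl.SearchParams(vdw_cutoff=2.5)
        with pytest.raises(ValueError, match="vdw_cutoff"):
            sl.SearchParams(vdw_cutoff=3.5)
        assert sl.SearchParams(vdw_cutoff=2.5, force=True).vdw_cutoff == 2.5

    def test_allowed_clashes_range(self):
        with pytest.raises(ValueError, match="allowed_clashes"):
            sl.SearchParams(allowed_clashes=6)
        assert sl.SearchParams(allowed_clashes=5).allowed_clashes == 5

    def test_trials_override(self):
        assert sl.SearchParams(thoroughness="quick", trials=37).n_trials == 37


class TestClashCount:
    def test_atom_beyond_cutoff_not_counted(self, template, attached):
        conf = sl.apply_torsions(attached, [180, 180, 180, 180, 90])
        pts = template.positions(conf.coordinates, template.side_chain_names)
        # put one env atom 3.5 A from the nearest label atom
        direction = np.array([0.0, 0.0, 1.0])
        probe = pts[0] + 3.5 * direction
        d = np.linalg.norm(pts - probe, axis=1).min()
        if d < 3.5:  # nudged into another atom; move along until clear
            probe = pts[:, :].mean(axis=0) + np.array([0, 0, 30.0])
        env = SpatialIndex([pseudo(probe)])
        assert clash_count(conf, env, 3.4, template) == 0

    def test_atom_inside_cutoff_counted_once(self, template, attached):
        conf = sl.apply_torsions(attached, [180, 180, 180, 180, 90])
        n1 = conf.coordinates[template.index("N1")]
        o1 = conf.coordinates[template.index("O1")]
        probe = n1 + 3.3 * (n1 - o1) / np.linalg.norm(n1 - o1)
        env = SpatialIndex([pseudo(probe)])
        assert clash_count(conf, env, 3.4, template) == 1

    def test_boundary_distance_is_not_a_clash(self, template, attached):
        """d == cutoff must not count (strict inequality)."""
        conf = sl.apply_torsions(attached, [180, 180, 180, 180, 90])
        pts = template.positions(conf.coordinates, template.side_chain_names)
        far = pts.mean(axis=0) + np.array([0.0, 0.0, 40.0])
        nearest = pts[np.linalg.norm(pts - far, axis=1).argmin()]
        u = (far - nearest) / np.linalg.norm(far - nearest)
        probe = nearest + 3.4 * u
        env = SpatialIndex([pseudo(probe)])
        assert clash_count(conf, env, 3.4, template) == 0
        assert clash_count(conf, env, 3.4 + 1e-9, template) == 1

    def test_wall_counts_match_brute_force(self, template, attached):
        rng = np.random.default_rng(21)
        conf = sl.apply_torsions(attached, rng.uniform(0, 360, 5))
        pts = template.positions(conf.coordinates, template.side_chain_names)
        center = pts.mean(axis=0)
        atoms = [pseudo(center + rng.uniform(-6, 6, 3), num=i) for i in range(100)]
        env = SpatialIndex(atoms)
        expected = 0
        for a in atoms:
            if np.linalg.norm(pts - a.position, axis=1).min() < 3.4:
                expected += 1
        assert clash_count(conf, env, 3.4, template) == expected

    def test_backbone_atoms_exempt(self, template, attached):
        """An env atom close only to the label's anchor region never clashes."""
        conf = sl.apply_torsions(attached, [180, 180, 180, 180, 90])
        ca = conf.coordinates[template.index("CA")]
        side = template.positions(conf.coordinates, template.side_chain_names)
        probe = ca + 0.9 * (ca - side.mean(axis=0)) / np.linalg.norm(ca - side.mean(axis=0))
        if np.linalg.norm(side - probe, axis=1).min() >= 3.4:
            env = SpatialIndex([pseudo(probe)])
            assert clash_count(conf, env, 3.4, template) == 0


class TestInternalClash:
    def test_reference_geometry_clean(self, template, attached):
        conf = sl.Conformer(chi=None, coordinates=attached.base_coordinates)
        assert not internal_clash(conf, 2.0, template)

    def test_folded_ring_detected(self, template, attached):
        """Grid-scan chi3/chi4 for the fold bringing the ring onto CB."""
        icb = template.index("CB")
        ring = [template.index(n) for n in ("C3", "C4", "C5", "N1", "C2")]
        best, best_conf = np.inf, None
        for chi3 in range(0, 360, 20):
            for chi4 in range(0, 360, 20):
                conf = sl.apply_torsions(attached, [180, 60, chi3, chi4, 90])
                d = np.linalg.norm(
                    conf.coordinates[ring] - conf.coordinates[icb], axis=1
                ).min()
                if d < best:
                    best, best_conf = d, conf
        assert best < 2.0
        assert internal_clash(best_conf, 2.0, template)

    def test_bonded_neighbors_never_flagged(self, template, attached):
        """1-2/1-3/1-4 proximities are exempt however tight the geometry."""
        conf = sl.apply_torsions(attached, [60, 300, 60, 300, 60])
        pairs = template.nonbonded_pairs(min_separation=4)
        sep = template.bond_graph_distances()
        for i, j in pairs:
            assert sep[i, j] >= 4


class TestRunSearch:
    def test_exposed_site_acceptance_in_pilot_band(self, gxg):
        """10-seed pilot on the exposed tripeptide froze 0.14-0.29 (mean 0.22)."""
        fracs = [
            sl.run_search(
                gxg, GXG_SITE, sl.SearchParams(thoroughness="normal", seed=s)
            ).acceptance_fraction
            for s in range(5)
        ]
        assert 0.08 <= np.mean(fracs) <= 0.45

    def test_cage_accepts_nothing(self):
        cage = sl.fixtures.make_cage(2.5)
        ens = sl.run_search(cage, GXG_SITE, sl.SearchParams(thoroughness="normal", seed=2))
        assert len(ens) == 0

    def test_same_seed_bit_identical(self, gxg):
        p = sl.SearchParams(thoroughness="normal", seed=9)
        e1 = sl.run_search(gxg, GXG_SITE, p)
        e2 = sl.run_search(gxg, GXG_SITE, p)
        assert len(e1) == len(e2)
        np.testing.assert_array_equal(e1.chi_matrix(), e2.chi_matrix())
        for c1, c2 in zip(e1.conformers, e2.conformers):
            np.testing.assert_array_equal(c1.coordinates, c2.coordinates)

    def test_accepted_conformers_satisfy_contracts(self, gxg_ensemble, gxg, template):
        """Re-assert clash_count <= allowed and no internal clash, post hoc."""
        env = SpatialIndex(environment_for_site(gxg, GXG_SITE))
        p = gxg_ensemble.params
        for conf in gxg_ensemble.conformers:
            assert not internal_clash(conf, p.internal_clash_cutoff, template)
            assert clash_count(conf, env, p.vdw_cutoff, template) <= p.allowed_clashes
            assert conf.clash_count <= p.allowed_clashes

    def test_cutoff_monotonicity_fixed_seed(self, gxg):
        """accepted(vdw 3.4) is a subset of accepted(vdw 2.6) trial-for-trial."""
        strict = sl.run_search(gxg, GXG_SITE, sl.SearchParams(vdw_cutoff=3.4, seed=4))
        loose = sl.run_search(gxg, GXG_SITE, sl.SearchParams(vdw_cutoff=2.6, seed=4))
        strict_chi = {tuple(np.round(c, 6)) for c in strict.chi_matrix()}
        loose_chi = {tuple(np.round(c, 6)) for c in loose.chi_matrix()}
        assert strict_chi <= loose_chi

    def test_allowed_clash_monotonicity_fixed_seed(self, gxg):
        wall = sl.fixtures.make_wall(8.0)
        sets = []
        for k in (0, 1, 2):
            e = sl.run_search(
                wall, GXG_SITE, sl.SearchParams(allowed_clashes=k, seed=4)
            )
            sets.append({tuple(np.round(c, 6)) for c in e.chi_matrix()})
        assert sets[0] <= sets[1] <= sets[2]

    def test_wall_impenetrability(self, template):
        """No accepted label atom comes within the cutoff of the wall."""
        wall = sl.fixtures.make_wall(10.0)
        ens = sl.run_search(wall, GXG_SITE, sl.SearchParams(thoroughness="thorough", seed=6))
        assert len(ens) > 0
        wall_atoms = np.array([
            a.position for a in wall.atoms if a.residue_name == "PSD"
        ])
        for conf in ens.conformers:
            pts = template.positions(conf.coordinates, template.side_chain_names)
            d = np.linalg.norm(pts[:, None] - wall_atoms[None], axis=2)
            assert d.min() >= ens.params.vdw_cutoff

    def test_cone_aperture_monotonicity(self):
        counts = {}
        for ap in (40.0, 160.0):
            cone = sl.fixtures.make_cone_pocket(ap)
            e = sl.run_search(cone, GXG_SITE, sl.SearchParams(thoroughness="thorough", seed=3))
            counts[ap] = len(e)
        assert counts[160.0] > counts[40.0]

    def test_acceptance_nondecreasing_in_trials(self, gxg):
        """More trials yield more accepted conformers in expectation."""
        short = [
            len(sl.run_search(gxg, GXG_SITE,
                              sl.SearchParams(thoroughness="quick", seed=s)))
            for s in range(5)
        ]
        long = [
            len(sl.run_search(gxg, GXG_SITE,
                              sl.SearchParams(thoroughness="normal", seed=s)))
            for s in range(5)
        ]
        assert np.mean(long) > np.mean(short)
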