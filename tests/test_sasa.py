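import itertools

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from perilesion.experiments import (
    build_synthetic_nucleosome,
    sasa_analytics_check,
)
from perilesion.periodicity import RotationalConfig
from perilesion.sasa_rotation import (
    StructureModel,
    VDW_RADII,
    compare_rotational_sasa,
    golden_spiral_points,
    mann_whitney,
    parse_structure,
    shrake_rupley_sasa,
)


class TestShrakeRupley:
    def test_isolated_sphere_matches_analytic_area(self):
        sasa = shrake_rupley_sasa(np.zeros((1, 3)), np.array([1.6]), 1.4, 960)
        assert sasa[0] == pytest.approx(4 * np.pi * 3.0**2, rel=5e-3)

    def test_fully_enclosed_atom_has_zero_sasa(self):
        shell = 3.0 * golden_spiral_points(200)
        coords = np.vstack([[0, 0, 0], shell])
        radii = np.concatenate([[1.0], np.full(200, 1.6)])
        sasa = shrake_rupley_sasa(coords, radii, 1.4, 960, atom_indices=[0])
        assert sasa[0] == 0.0

    def test_two_sphere_overlap_matches_cap_formula(self):
        r, probe, d = 1.6, 1.4, 3.0
        R = r + probe
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        sasa = shrake_rupley_sasa(coords, np.array([r, r]), probe, 960)
        expected = 4 * np.pi * R**2 - 2 * np.pi * R * (R - d / 2)
        np.testing.assert_allclose(sasa, expected, rtol=1e-2)

    def test_rotation_translation_invariance(self, rng):
        coords = rng.normal(0, 2, (15, 3))
        radii = rng.uniform(1.2, 1.8, 15)
        base = shrake_rupley_sasa(coords, radii, 1.4, 384)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = coords @ q.T + [10.0, -4.0, 7.0]
        again = shrake_rupley_sasa(moved, radii, 1.4, 384)
        np.testing.assert_allclose(again, base, rtol=1e-6)

    def test_adding_neighbors_never_increases_sasa(self, rng):
        coords = rng.normal(0, 2.5, (10, 3))
        radii = np.full(10, 1.5)
        # fixed frame: occlusion sets are nested, so monotonicity is exact
        few = shrake_rupley_sasa(coords[:5], radii[:5], 1.4, 384, canonical=False)
        more = shrake_rupley_sasa(
            coords, radii, 1.4, 384, atom_indices=np.arange(5), canonical=False
        )
        assert np.all(more[:5] <= few + 1e-9)

    def test_point_count_convergence_on_two_sphere_case(self):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        radii = np.array([1.6, 1.6])
        a = shrake_rupley_sasa(coords, radii, 1.4, 960)
        b = shrake_rupley_sasa(coords, radii, 1.4, 3840)
        assert np.abs(a - b).max() / b.max() < 0.01

    def test_agrees_with_biotite_reference(self, rng):
        """Independent cross-check against biotite's Shrake-Rupley."""
        import biotite.structure as struc

        n = 20
        coords = rng.normal(0, 3, (n, 3))
        radii = np.full(n, 1.7)
        ours = shrake_rupley_sasa(coords, radii, 1.4, 960)
        atoms = struc.AtomArray(n)
        atoms.coord = coords
        atoms.element = np.full(n, "C")
        atoms.atom_name = np.full(n, "C")
        atoms.res_name = np.full(n, "UNK")
        atoms.res_id = np.arange(n)
        atoms.chain_id = np.full(n, "A")
        atoms.hetero = np.full(n, True)
        ref = struc.sasa(atoms, probe_radius=1.4, point_number=960, vdw_radii="Single")
        # both are stochastic-free quadratures; agreement within a few %
        np.testing.assert_allclose(ours, ref, rtol=0.05, atol=1.0)


class TestMannWhitney:
    def test_textbook_separation_example(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0 and p == pytest.approx(0.1)

    def test_u_identity(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(size=5)
        ua, _ = mann_whitney(a, b)
        ub, _ = mann_whitney(b, a)
        assert ua + ub == pytest.approx(len(a) * len(b))

    def test_identical_groups_p_one(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_exact_p_equals_enumeration_for_all_small_sizes(self):
        rng = np.random.default_rng(2)
        for na in range(1, 7):
            for nb in range(1, 7):
                vals = rng.permutation(np.arange(na + nb) * 1.7 + 0.3)
                a, b = vals[:na], vals[na:]
                _, p = mann_whitney(a, b)
                combined = np.concatenate([a, b])
                mean = na * nb / 2

                def u_of(idx):
                    grp = combined[list(idx)]
                    rest = np.delete(combined, list(idx))
                    return (grp[:, None] > rest[None, :]).sum()

                dev = abs(u_of(tuple(range(na))) - mean)
                hits = sum(
                    1
                    for idx in itertools.combinations(range(na + nb), na)
                    if abs(u_of(idx) - mean) >= dev - 1e-9
                )
                total = len(list(itertools.combinations(range(na + nb), na)))
                assert p == pytest.approx(hits / total, abs=1e-12)

    def test_large_sample_approximation_tracks_scipy(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.5, 1, 35)
        u, p = mann_whitney(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestStructureParsing:
    def _write_pdb(self, path, atoms):
        import biotite.structure as struc
        from biotite.structure.io.pdb import PDBFile

        arr = struc.AtomArray(len(atoms))
        for k, (name, res, rid, elem, xyz) in enumerate(atoms):
            arr.atom_name[k] = name
            arr.res_name[k] = res
            arr.res_id[k] = rid
            arr.element[k] = elem
            arr.coord[k] = xyz
            arr.chain_id[k] = "I"
        pdb = PDBFile()
        pdb.set_structure(arr)
        pdb.write(str(path))

    def test_minimal_guanine_residue(self, tmp_path):
        p = tmp_path / "m.pdb"
        self._write_pdb(
            p,
            [
                ("N2", "DG", 1, "N", (0.0, 0, 0)),
                ("C2", "DG", 1, "C", (1.4, 0, 0)),
            ],
        )
        model = parse_structure(p)
        assert model.n_atoms == 2
        assert list(model.guanine_n2_indices()) == [0]

    def test_guanine_without_n2_excluded_with_warning(self, tmp_path):
        p = tmp_path / "m.pdb"
        self._write_pdb(
            p,
            [
                ("C2", "DG", 1, "C", (0.0, 0, 0)),
                ("N2", "DG", 2, "N", (5.0, 0, 0)),
            ],
        )
        with pytest.warns(UserWarning, match="excluded"):
            model = parse_structure(p)
        assert model.n_atoms == 1

    def test_unknown_element_is_error(self, tmp_path):
        p = tmp_path / "m.pdb"
        self._write_pdb(p, [("FE", "HEM", 1, "Fe", (0.0, 0, 0))])
        with pytest.raises(ValueError, match="Fe"):
            parse_structure(p)


class TestRotationalSasaComparison:
    def test_constructed_geometry_favors_minor_out(self):
        model = build_synthetic_nucleosome()
        cfg = RotationalConfig(10.2, 0.0, core_half_width=10_000)
        cmp = compare_rotational_sasa(model, cfg, n_points=384)
        assert cmp.median_ratio > 1
        assert cmp.p_value < 0.05

    def test_structure_without_guanines_is_error(self):
        model = StructureModel(
            coords=np.zeros((1, 3)),
            radii=np.array([1.7]),
            elements=np.array(["C"]),
            atom_names=np.array(["C1"]),
            res_names=np.array(["COR"]),
            chain_ids=np.array(["Z"]),
            res_ids=np.array([1]),
        )
        with pytest.raises(ValueError):
            compare_rotational_sasa(model)

    def test_sasa_analytics_bundle(self):
        res = sasa_analytics_check(n_points=960)
        assert res.isolated_rel_error < 0.005
        assert res.two_sphere_rel_error < 0.01
        assert res.rotation_invariance_rel_error < 1e-6
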