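"""SASA, hydrophobic fractions and per-surface water densities."""

import numpy as np
import pytest

from afpshell import (SurfaceSelection, compute_sasa, hydrophobic_fraction,
                      selection_sasa, surface_water_count)
from afpshell.structure_io import AtomRecord, Topology


class TestSASA:
    def test_isolated_sphere(self):
        res = compute_sasa(np.zeros((1, 3)), np.array([0.15]), probe=0.14)
        assert res.total_S == pytest.approx(4 * np.pi * 0.29 ** 2, rel=1e-9)

    def test_buried_atom_has_zero_area(self):
        # central atom caged by 14 large neighbours
        shell = []
        for s in (-1, 1):
            for ax in range(3):
                v = np.zeros(3)
                v[ax] = s * 0.25
                shell.append(v)
        for sx in (-1, 1):
            for sy in (-1, 1):
                for sz in (-1, 1):
                    shell.append(0.16 * np.array([sx, sy, sz]))
        coords = np.vstack([np.zeros(3), shell])
        radii = np.array([0.1] + [0.2] * len(shell))
        res = compute_sasa(coords, radii, probe=0.14)
        assert res.per_atom_area[0] == 0.0

    def test_two_sphere_overlap_vs_spherical_cap(self):
        # equal accessible radii R at separation d: each loses a cap of
        # height h = R - d/2; exposed area per atom = 4 pi R^2 - 2 pi R h
        R, d = 0.29, 0.35
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        res = compute_sasa(coords, np.array([0.15, 0.15]), probe=0.14,
                           n_points=960)
        h = R - d / 2
        expected = 4 * np.pi * R ** 2 - 2 * np.pi * R * h
        assert res.per_atom_area[0] == pytest.approx(expected, rel=0.01)
        assert res.per_atom_area[1] == pytest.approx(expected, rel=0.01)

    def test_point_count_convergence(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 1.2, (100, 3))
        radii = rng.uniform(0.12, 0.18, 100)
        s1 = compute_sasa(coords, radii, n_points=960).total_S
        s2 = compute_sasa(coords, radii, n_points=1920).total_S
        assert abs(s2 - s1) / s1 < 0.003

    def test_missing_radius_rejected(self):
        with pytest.raises(ValueError, match="radii"):
            compute_sasa(np.zeros((1, 3)), np.array([np.nan]))


class TestHydrophobicFraction:
    def sasa_two_atoms(self):
        return compute_sasa(np.array([[0.0, 0, 0], [5.0, 0, 0]]),
                            np.array([0.15, 0.15]))

    def test_all_nonpolar(self):
        res = hydrophobic_fraction(self.sasa_two_atoms(), np.zeros(2))
        assert res.fraction_pho == 1.0

    def test_all_polar(self):
        res = hydrophobic_fraction(self.sasa_two_atoms(), np.array([0.5, -0.5]))
        assert res.fraction_pho == 0.0

    def test_two_atom_known_areas(self):
        sasa = self.sasa_two_atoms()
        res = hydrophobic_fraction(sasa, np.array([0.1, 0.5]))
        a1, a2 = sasa.per_atom_area
        assert res.fraction_pho == pytest.approx(a1 / (a1 + a2))
        assert res.S_pho == pytest.approx(a1)

    def test_threshold_inclusive_at_boundary(self):
        # "between -0.2 and 0.2" treated inclusively: |q| = 0.2 is nonpolar
        res = hydrophobic_fraction(self.sasa_two_atoms(), np.array([0.2, -0.2]))
        assert res.fraction_pho == 1.0


class TestSelectionSASA:
    def test_partition_and_completeness(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 1.0, (30, 3))
        sasa = compute_sasa(coords, np.full(30, 0.15))
        ibs_idx = np.arange(10)
        nibs_idx = np.arange(10, 30)
        s_ibs = selection_sasa(sasa, ibs_idx)
        s_nibs = selection_sasa(sasa, nibs_idx)
        assert s_ibs + s_nibs == pytest.approx(sasa.total_S, rel=1e-12)
        assert selection_sasa(sasa, np.arange(30)) == pytest.approx(sasa.total_S)

    def test_three_residue_peptide_direct_sum(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 0.8, (9, 3))
        atoms = [AtomRecord(i, f"C{i}", "C", i // 3 + 1, "ALA", "A",
                            vdw_radius=0.15, partial_charge=0.0)
                 for i in range(9)]
        topo = Topology(atoms)
        sel = SurfaceSelection("IBS", frozenset({("A", 1)}))
        sasa = compute_sasa(coords, np.full(9, 0.15))
        idx = sel.atom_indices(topo)
        assert np.array_equal(idx, [0, 1, 2])
        assert selection_sasa(sasa, idx) == pytest.approx(
            sasa.per_atom_area[:3].sum())

    def test_empty_selection_rejected(self):
        sasa = compute_sasa(np.zeros((1, 3)), np.array([0.15]))
        with pytest.raises(ValueError, match="empty"):
            selection_sasa(sasa, np.array([], dtype=int))


class TestSurfaceWaterCount:
    BOX = np.array([8.0, 8.0, 8.0])

    @pytest.mark.parametrize("dist,expected", [(0.54, 1), (0.56, 0)])
    def test_cutoff_boundary(self, dist, expected):
        sel = np.array([[4.0, 4.0, 4.0]])
        wat = np.array([[4.0 + dist, 4.0, 4.0]])
        assert surface_water_count(wat, sel, self.BOX, 0.55) == expected

    def test_water_near_two_atoms_counted_once(self):
        sel = np.array([[4.0, 4.0, 4.0], [4.4, 4.0, 4.0]])
        wat = np.array([[4.2, 4.0, 4.0]])
        assert surface_water_count(wat, sel, self.BOX, 0.55) == 1

    def test_periodic_images_seen(self):
        sel = np.array([[0.1, 4.0, 4.0]])
        wat = np.array([[7.8, 4.0, 4.0]])  # 0.3 nm away through the boundary
        assert surface_water_count(wat, sel, self.BOX, 0.55) == 1

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        sel = rng.uniform(3, 5, (40, 3))
        wat = rng.uniform(0, 8, (1000, 3))
        n = surface_water_count(wat, sel, self.BOX, 0.55)
        d = wat[:, None, :] - sel[None, :, :]
        d -= self.BOX * np.round(d / self.BOX)
        hit = (np.linalg.norm(d, axis=2) <= 0.55).any(axis=1)
        assert n == int(hit.sum())


class TestSurfaceDensityArithmetic:
    def test_identity_and_scaling(self, small_hydrated):
        from afpshell import sasa_series, surface_density
        from afpshell.structure_io import load_selection
        spec, traj, mimic = small_hydrated
        sasa = sasa_series(traj)
        ibs, _ = load_selection({"ibs_residues": mimic.ibs_residues()},
                                traj.topology)
        res = surface_density(traj, ibs, sasa, traj)  # fict == real
        assert res.eta_surf == pytest.approx(0.0, abs=1e-12)
        assert res.rho_surf == pytest.approx(res.N_w_mean / res.S_mean, rel=1e-12)
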