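"""Density profiles, fictitious overlays, ratio profiles and plateaus."""

import numpy as np
import pytest

from afpshell import (EllipsoidModel, Trajectory, compute_density_profile,
                      detect_plateau, make_fictitious_configs, ratio_profile)
from afpshell.profiles import RatioProfile
from afpshell.structure_io import AtomRecord, Frame, Topology
from conftest import oxygen_only_trajectory

BOX = np.array([10.0, 10.0, 10.0])
SPHERE = EllipsoidModel(center=BOX / 2, axes=np.eye(3),
                        semi_axes=np.array([1.0, 1.0, 1.0]))


def test_no_waters_gives_zero_density():
    traj = oxygen_only_trajectory([np.zeros((0, 3))], BOX)
    prof = compute_density_profile(traj, SPHERE, bin_width=0.1, d_max=2.0)
    assert np.all(prof.density == 0)


def test_uniform_poisson_matches_density():
    # bulk-distributed waters: every bin within 3 Poisson SE of rho0
    rng = np.random.default_rng(0)
    rho0 = 20.0
    frames = [rng.uniform(0, 10, (rng.poisson(rho0 * 1000), 3)) for _ in range(40)]
    traj = oxygen_only_trajectory(frames, BOX)
    prof = compute_density_profile(traj, SPHERE, bin_width=0.1, d_max=2.0)
    n_tot = prof.counts * prof.n_frames
    se = np.sqrt(np.maximum(n_tot, 1)) / prof.n_frames / prof.bin_volumes
    assert np.all(np.abs(prof.density - rho0) < 3.2 * se)


def test_slab_construction_localised():
    # waters exactly in the [0.2, 0.4) distance slab around a sphere
    rng = np.random.default_rng(1)
    n = 500
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = 1.0 + rng.uniform(0.2, 0.4 - 1e-9, n)
    traj = oxygen_only_trajectory([BOX / 2 + u * r[:, None]], BOX)
    prof = compute_density_profile(traj, SPHERE, bin_width=0.1, d_max=1.0)
    nonzero = prof.counts > 0
    assert nonzero.tolist() == [False, False, True, True, False, False,
                                False, False, False, False]
    assert prof.counts[2:4].sum() == n


def test_bin_volume_consistency():
    rng = np.random.default_rng(2)
    traj = oxygen_only_trajectory([rng.uniform(0, 10, (500, 3))], BOX)
    prof = compute_density_profile(traj, SPHERE, bin_width=0.2, d_max=1.0)
    assert np.allclose(prof.density * prof.bin_volumes * prof.n_frames,
                       prof.counts * prof.n_frames)


def test_shell_crossing_box_rejected():
    small = np.array([3.0, 3.0, 3.0])
    traj = oxygen_only_trajectory([np.ones((1, 3))], small)
    sphere = EllipsoidModel(center=small / 2, axes=np.eye(3),
                            semi_axes=np.array([1.0, 1.0, 1.0]))
    with pytest.raises(ValueError, match="periodic"):
        compute_density_profile(traj, sphere, bin_width=0.1, d_max=2.0)


class TestFictitious:
    def protein_traj(self, coords, box=BOX):
        atoms = [AtomRecord(i, f"C{i+1}", "C", i + 1, "PRT", "A",
                            vdw_radius=0.17, partial_charge=0.0)
                 for i in range(len(coords))]
        return Trajectory(Topology(atoms),
                          [Frame(np.asarray(coords, float), box)])

    def test_no_protein_is_identity(self):
        rng = np.random.default_rng(3)
        bulk = oxygen_only_trajectory([rng.uniform(0, 10, (200, 3))], BOX)
        empty = self.protein_traj(np.zeros((0, 3)))
        fict = make_fictitious_configs(empty, bulk)
        ow = fict.frame_mask(fict.frames[0], fict.topology.is_water_oxygen)
        assert len(ow) == 200

    @pytest.mark.parametrize("dist,kept", [(0.32, False), (0.33, True)])
    def test_removal_threshold(self, dist, kept):
        # protein r=0.17 + water O r=0.152 -> clash below 0.322 nm
        prot = self.protein_traj([[5.0, 5.0, 5.0]])
        bulk = oxygen_only_trajectory([[[5.0 + dist, 5.0, 5.0]]], BOX)
        fict = make_fictitious_configs(prot, bulk)
        ow = fict.frame_mask(fict.frames[0], fict.topology.is_water_oxygen)
        assert (len(ow) == 1) is kept

    def test_removal_matches_brute_force(self):
        rng = np.random.default_rng(4)
        prot_xyz = rng.uniform(4, 6, (30, 3))
        wat_xyz = rng.uniform(0, 10, (400, 3))
        prot = self.protein_traj(prot_xyz)
        bulk = oxygen_only_trajectory([wat_xyz], BOX)
        fict = make_fictitious_configs(prot, bulk)
        ow = fict.frame_mask(fict.frames[0], fict.topology.is_water_oxygen)
        # brute force with minimum image
        d = wat_xyz[:, None, :] - prot_xyz[None, :, :]
        d -= BOX * np.round(d / BOX)
        removed = (np.linalg.norm(d, axis=2) < 0.17 + 0.152).any(axis=1)
        keep_expected = wat_xyz[~removed]
        assert len(ow) == len(keep_expected)
        assert np.allclose(np.sort(ow, axis=0), np.sort(keep_expected, axis=0))
        # conservation: out = in - removed, exactly
        assert len(ow) == 400 - removed.sum()

    def test_unassigned_radius_rejected(self):
        prot = self.protein_traj([[5.0, 5.0, 5.0]])
        prot.topology.atoms[0].vdw_radius = None
        prot.topology._invalidate()
        bulk = oxygen_only_trajectory([[[1.0, 1.0, 1.0]]], BOX)
        with pytest.raises(ValueError, match="radii"):
            make_fictitious_configs(prot, bulk)

    def test_empty_bulk_rejected(self):
        prot = self.protein_traj([[5.0, 5.0, 5.0]])
        bulk = oxygen_only_trajectory([np.zeros((0, 3))], BOX)
        with pytest.raises(ValueError, match="bulk"):
            make_fictitious_configs(prot, bulk)


class TestRatio:
    def profile_pair(self, factor):
        rng = np.random.default_rng(5)
        frames = [rng.uniform(0, 10, (2000, 3)) for _ in range(5)]
        traj = oxygen_only_trajectory(frames, BOX)
        real = compute_density_profile(traj, SPHERE, bin_width=0.2, d_max=1.0)
        fict = compute_density_profile(traj, SPHERE, bin_width=0.2, d_max=1.0)
        real.counts = real.counts * factor
        real.density = real.density * factor
        if real.counts_per_frame is not None:
            real.counts_per_frame = real.counts_per_frame * factor
        return real, fict

    def test_identity_gives_unity(self):
        real, fict = self.profile_pair(1.0)
        rp = ratio_profile(real, fict)
        assert np.allclose(rp.ratio[rp.defined], 1.0)

    def test_scaling(self):
        real, fict = self.profile_pair(1.1)
        rp = ratio_profile(real, fict)
        assert np.allclose(rp.ratio[rp.defined], 1.1)

    def test_binning_mismatch_rejected(self):
        real, _ = self.profile_pair(1.0)
        rng = np.random.default_rng(6)
        other = compute_density_profile(
            oxygen_only_trajectory([rng.uniform(0, 10, (100, 3))], BOX),
            SPHERE, bin_width=0.25, d_max=1.0)
        with pytest.raises(ValueError, match="binning"):
            ratio_profile(real, other)

    def test_zero_fictitious_flagged_not_infinite(self):
        real, fict = self.profile_pair(1.0)
        fict.counts = fict.counts.copy()
        fict.counts[0] = 0.0
        rp = ratio_profile(real, fict)
        assert not rp.defined[0] and np.isnan(rp.ratio[0])
        assert np.isfinite(rp.ratio[rp.defined]).all()


class TestPlateau:
    def make_rp(self, ratio):
        ratio = np.asarray(ratio, float)
        edges = np.arange(len(ratio) + 1) * 0.2
        return RatioProfile(bin_edges=edges, ratio=ratio,
                            stderr=np.zeros_like(ratio),
                            defined=np.ones(len(ratio), bool))

    def test_flat_unity_starts_at_first_edge(self):
        res = detect_plateau(self.make_rp(np.ones(10)), tol=0.02, run_length=3)
        assert res.found and res.distance == 0.0

    def test_step_profile(self):
        ratio = np.where(np.arange(10) < 5, 1.1, 1.0)  # 1.1 below 1 nm
        res = detect_plateau(self.make_rp(ratio), tol=0.02, run_length=3)
        assert res.found and res.distance == pytest.approx(1.0)

    def test_missing_plateau_flagged(self):
        res = detect_plateau(self.make_rp(np.full(10, 1.3)), tol=0.02, run_length=3)
        assert not res.found and res.distance is None

    def test_noisy_decay_recovery_over_seeds(self):
        # eta(d) = 0.1 exp(-d/0.25): drops below tol=0.03 at ~0.30 nm
        edges = np.arange(0, 2.01, 0.1)
        mid = 0.5 * (edges[:-1] + edges[1:])
        truth = 1.0 + 0.1 * np.exp(-mid / 0.25)
        true_plateau = edges[np.argmax(np.abs(truth - 1) < 0.03)]
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = truth + rng.normal(0, 0.004, len(mid))
            rp = RatioProfile(bin_edges=edges, ratio=noisy,
                              stderr=np.full_like(mid, 0.004),
                              defined=np.ones(len(mid), bool))
            res = detect_plateau(rp, tol=0.03, run_length=4)
            if res.found and abs(res.distance - true_plateau) <= 0.1:
                hits += 1
        assert hits >= 90
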