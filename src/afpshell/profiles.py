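"""Solvent density vs distance from the ellipsoid surface.

Real profiles come from the MD (or synthetic) configurations; reference
profiles come from "fictitious" configurations in which the protein is
overlaid on bulk-water frames and overlapping waters removed.  Their ratio
rho / rho_b,fict cancels the geometric effects of protein atoms protruding
through the ellipsoid surface, so it reads directly as the relative water
density with respect to bulk at each distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .ellipsoid import EllipsoidModel, parallel_body_volume, signed_surface_distance
from .structure_io import Frame, Topology, Trajectory, minimum_image

logger = logging.getLogger("afpshell")

__all__ = [
    "DensityProfile", "RatioProfile", "PlateauResult",
    "compute_density_profile", "make_fictitious_configs",
    "ratio_profile", "detect_plateau",
    "water_oxygen_positions", "check_shell_fits_box",
]


@dataclass
class DensityProfile:
    """Binned solvent density vs distance from the ellipsoid surface.

    counts are mean water-oxygen counts per bin per frame; bin_volumes are
    geometric parallel-body slab volumes (nm^3); density = counts/bin_volumes
    in molecules nm^-3.
    """

    bin_edges: np.ndarray           # (n_bins + 1,), nm, half-open [lo, hi)
    counts: np.ndarray              # (n_bins,), mean per frame
    bin_volumes: np.ndarray         # (n_bins,), nm^3
    density: np.ndarray             # (n_bins,), nm^-3
    n_frames: int
    counts_per_frame: np.ndarray | None = None   # (n_frames, n_bins)

    def __post_init__(self) -> None:
        if np.any(self.bin_volumes <= 0):
            raise ValueError("bin volumes must be positive")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")

    @property
    def bin_mid(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class RatioProfile:
    """Per-bin rho/rho_b,fict with standard errors; undefined bins flagged."""

    bin_edges: np.ndarray
    ratio: np.ndarray               # nan where undefined
    stderr: np.ndarray
    defined: np.ndarray             # bool per bin

    @property
    def bin_mid(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class PlateauResult:
    found: bool
    distance: float | None          # nm, bin edge where the plateau starts


def water_oxygen_positions(traj: Trajectory, frame: Frame) -> np.ndarray:
    """Water-oxygen coordinates of a frame (honouring removed-water masks)."""
    return traj.frame_mask(frame, traj.topology.is_water_oxygen)


def check_shell_fits_box(ellipsoid: EllipsoidModel, d_max: float, box: np.ndarray) -> None:
    """Refuse geometries whose d_max shell could touch its periodic image."""
    reach = float(ellipsoid.semi_axes[0]) + d_max
    if 2.0 * reach > float(np.min(box)):
        raise ValueError(
            f"shell of reach {reach:.2f} nm does not fit in box {box} "
            "(would cross the periodic boundary); enlarge the box or reduce d_max"
        )


def _relative_to_center(points: np.ndarray, center: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Re-image points so they sit in the box image nearest the ellipsoid center."""
    return center + minimum_image(points - center, box)


def compute_density_profile(traj: Trajectory, ellipsoid: EllipsoidModel,
                            bin_width: float = 0.02, d_max: float = 2.0,
                            keep_frame_counts: bool = True) -> DensityProfile:
    """Histogram water oxygens by signed distance from the ellipsoid surface.

    Bins are half-open [d, d + bin_width) on [0, d_max); bin volumes are
    parallel-body volume differences; counts are averaged over frames.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if d_max < 1.0:
        raise ValueError("d_max must be >= 1 nm (the shell extends to 1 nm)")
    n_bins = int(round(d_max / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    vols = np.array([parallel_body_volume(ellipsoid, t) for t in edges])
    bin_volumes = np.diff(vols)

    per_frame = np.zeros((traj.n_frames, n_bins))
    for i, fr in enumerate(traj.frames):
        check_shell_fits_box(ellipsoid, d_max, fr.box)
        ow = water_oxygen_positions(traj, fr)
        if len(ow) == 0:
            continue
        ow = _relative_to_center(ow, ellipsoid.center, fr.box)
        d = signed_surface_distance(ow, ellipsoid)
        per_frame[i], _ = np.histogram(d, bins=edges)
    counts = per_frame.mean(axis=0) if traj.n_frames else np.zeros(n_bins)
    return DensityProfile(
        bin_edges=edges,
        counts=counts,
        bin_volumes=bin_volumes,
        density=counts / bin_volumes,
        n_frames=traj.n_frames,
        counts_per_frame=per_frame if keep_frame_counts else None,
    )


def make_fictitious_configs(protein_frames: Trajectory, bulk_frames: Trajectory,
                            pairing=None) -> Trajectory:
    """Overlay protein coordinates on bulk-water frames; drop clashing waters.

    Output frame i carries the protein atoms of protein frame i and the
    waters of bulk frame pairing(i) (default: i modulo the bulk frame
    count), minus every water molecule having ANY atom within the sum of
    vdW radii (minimum image) of ANY protein atom.  Waters are removed as
    whole molecules; the water content of each output frame is therefore
    bulk-distributed wherever the protein permits.
    """
    p_topo = protein_frames.topology
    b_topo = bulk_frames.topology
    if bulk_frames.n_frames == 0 or all(
            len(fr.coordinates) == 0 for fr in bulk_frames.frames):
        raise ValueError("bulk trajectory has no water frames")
    prot_mask = p_topo.is_protein
    prot_idx = np.flatnonzero(prot_mask)
    prot_radii = p_topo.vdw_radii[prot_idx]
    if np.any(np.isnan(prot_radii)):
        raise ValueError("protein atoms lack vdW radii; run assign_parameters first")
    wat_radii = b_topo.vdw_radii
    if np.any(np.isnan(wat_radii[b_topo.is_water])):
        raise ValueError("bulk water atoms lack vdW radii; run assign_parameters first")

    # group bulk water atoms into molecules (contiguous per residue)
    mol_key = {}
    mol_of_atom = np.full(len(b_topo), -1, dtype=int)
    for ai, a in enumerate(b_topo):
        if a.is_water:
            key = (a.chain_id, a.residue_id)
            mol_of_atom[ai] = mol_key.setdefault(key, len(mol_key))
    n_mols = len(mol_key)
    wat_atoms = np.flatnonzero(mol_of_atom >= 0)

    if pairing is None:
        pairing = lambda i: i % bulk_frames.n_frames  # noqa: E731

    # combined topology: protein atoms then bulk atoms; frames mask waters
    combined_atoms = [p_topo[int(i)] for i in prot_idx] + list(b_topo.atoms)
    out_topo = Topology(combined_atoms)
    n_prot = len(prot_idx)

    out_frames = []
    for i, pfr in enumerate(protein_frames.frames):
        bfr = bulk_frames.frames[pairing(i)]
        box = bfr.box
        if np.any(pfr.box > box + 1e-9):
            raise ValueError("bulk box must be at least as large as the protein box")
        prot_pos = pfr.coordinates[np.isin(pfr.indices(len(p_topo)), prot_idx)]
        idx_b = bfr.indices(len(b_topo))
        wat_rows = np.flatnonzero(mol_of_atom[idx_b] >= 0)
        wat_topo_atoms = idx_b[wat_rows]
        wat_pos = bfr.coordinates[wat_rows]
        r_w = wat_radii[wat_topo_atoms]
        mols_here = mol_of_atom[wat_topo_atoms]

        removed_mols = np.zeros(n_mols, dtype=bool)
        if len(prot_pos) and len(wat_pos):
            max_cut = float(prot_radii.max() + r_w.max())
            tree = cKDTree(np.mod(wat_pos, box), boxsize=box)
            for pj, ppos in enumerate(np.mod(prot_pos, box)):
                cand = tree.query_ball_point(ppos, r=max_cut)
                if not cand:
                    continue
                cand = np.asarray(cand)
                dv = minimum_image(wat_pos[cand] - prot_pos[pj], box)
                dist = np.linalg.norm(dv, axis=1)
                clash = dist < (prot_radii[pj] + r_w[cand])
                removed_mols[mols_here[cand[clash]]] = True

        keep_atom = ~removed_mols[mols_here]
        kept_bulk_rows = wat_topo_atoms[keep_atom]
        # non-water bulk atoms (none normally) are dropped
        coords = np.vstack([prot_pos, wat_pos[keep_atom]]) if len(prot_pos) else wat_pos[keep_atom]
        atom_index = np.concatenate([np.arange(n_prot), n_prot + kept_bulk_rows])
        out_frames.append(Frame(coordinates=coords, box=box, time=pfr.time,
                                atom_index=atom_index))
        n_removed = int(removed_mols.sum())
        logger.debug("fictitious frame %d: removed %d of %d waters", i, n_removed, n_mols)
    return Trajectory(topology=out_topo, frames=out_frames)


def ratio_profile(real: DensityProfile, fict: DensityProfile) -> RatioProfile:
    """Per-bin rho/rho_b,fict with standard errors from per-frame spread."""
    if real.bin_edges.shape != fict.bin_edges.shape or not np.allclose(
            real.bin_edges, fict.bin_edges):
        raise ValueError("real and fictitious profiles must share binning")
    defined = fict.counts > 0
    ratio = np.full_like(real.density, np.nan)
    ratio[defined] = real.counts[defined] / fict.counts[defined]

    def _se(prof: DensityProfile) -> np.ndarray:
        if prof.counts_per_frame is None or prof.n_frames < 2:
            return np.zeros_like(prof.counts)
        return prof.counts_per_frame.std(axis=0, ddof=1) / np.sqrt(prof.n_frames)

    se_r, se_f = _se(real), _se(fict)
    stderr = np.full_like(ratio, np.nan)
    ok = defined & (real.counts > 0)
    stderr[ok] = ratio[ok] * np.sqrt(
        (se_r[ok] / real.counts[ok]) ** 2 + (se_f[ok] / fict.counts[ok]) ** 2
    )
    stderr[defined & ~ok] = se_r[defined & ~ok] / fict.counts[defined & ~ok]
    return RatioProfile(bin_edges=real.bin_edges.copy(), ratio=ratio,
                        stderr=stderr, defined=defined)


def detect_plateau(rp: RatioProfile, tol: float = 0.02, run_length: int = 3) -> PlateauResult:
    """Smallest bin-edge distance after which |ratio - 1| < tol holds for
    run_length consecutive bins.  Diagnostic for the 1 nm shell thickness;
    a missing plateau is a flagged result, not an exception."""
    ok = rp.defined & (np.abs(rp.ratio - 1.0) < tol)
    n = len(ok)
    if run_length < 1 or run_length > n:
        raise ValueError("run_length must be between 1 and the number of bins")
    for j in range(0, n - run_length + 1):
        if ok[j:j + run_length].all():
            return PlateauResult(found=True, distance=float(rp.bin_edges[j]))
    return PlateauResult(found=False, distance=None)
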