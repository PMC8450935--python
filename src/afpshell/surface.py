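"""Per-surface metrics: SASA, hydrophobic fractions, and local densities.

The ice-binding surface (IBS) and the remaining surface (NIBS) are residue
selections.  For each, the local solvent density is

    rho_surf = <N_w> / <S>

with N_w the number of water molecules whose oxygen lies within a cutoff
(default 0.55 nm) of any heavy atom of the selection, and S the selection's
solvent-accessible surface area, both averaged over frames (ratio of means).
The relative increment eta_surf = rho_surf / rho_surf_fict - 1 references the
same count performed on fictitious bulk-overlay configurations.

Hydrophobicity follows the partial-charge rule: atoms with |q| <= 0.2 e are
nonpolar, and S_pho is their summed exposed area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .shell import subtrajectory_errors
from .structure_io import Frame, SurfaceSelection, Trajectory, minimum_image

__all__ = [
    "SASAResult", "SurfaceDensityResult",
    "compute_sasa", "hydrophobic_fraction", "selection_sasa",
    "surface_water_count", "surface_density", "sasa_series",
]


@dataclass
class SASAResult:
    """Per-atom and total solvent-accessible surface areas (nm^2)."""

    per_atom_area: np.ndarray
    total_S: float
    S_pho: float | None = None
    fraction_pho: float | None = None

    def __post_init__(self) -> None:
        if np.any(self.per_atom_area < 0):
            raise ValueError("per-atom areas must be non-negative")
        if abs(self.total_S - float(self.per_atom_area.sum())) > 1e-9 * max(1.0, self.total_S):
            raise ValueError("total_S must equal the per-atom sum")


@dataclass
class SurfaceDensityResult:
    """Local density result for one surface selection."""

    selection_label: str
    N_w_mean: float
    S_mean: float
    rho_surf: float            # nm^-2
    rho_surf_fict: float       # nm^-2
    eta_surf: float
    errors: dict


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Near-uniform unit-sphere point set (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def compute_sasa(coords: np.ndarray, radii: np.ndarray, probe: float = 0.14,
                 n_points: int = 960) -> SASAResult:
    """Shrake–Rupley SASA with n_points test points per atom.

    Each atom's accessible sphere has radius r_i + probe; a test point is
    exposed when outside every neighbour's accessible sphere.  Per-atom
    areas sum exactly to the total.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float).reshape(-1)
    if len(coords) != len(radii):
        raise ValueError("coords and radii must align")
    if np.any(np.isnan(radii)) or np.any(radii <= 0):
        raise ValueError("all atoms need positive vdW radii (run assign_parameters)")
    n_atoms = len(coords)
    r_acc = radii + probe
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    r_max = float(r_acc.max())
    areas = np.empty(n_atoms)
    for i in range(n_atoms):
        neigh = tree.query_ball_point(coords[i], r=r_acc[i] + r_max)
        neigh = [j for j in neigh if j != i]
        pts = coords[i] + r_acc[i] * sphere
        if neigh:
            nb = np.asarray(neigh)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(-1)
            exposed = (d2 > (r_acc[nb] ** 2)[None, :]).all(axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * r_acc[i] ** 2 * frac
    return SASAResult(per_atom_area=areas, total_S=float(areas.sum()))


def hydrophobic_fraction(sasa: SASAResult, charges: np.ndarray,
                         threshold: float = 0.2) -> SASAResult:
    """Attach S_pho (area of atoms with |q| <= threshold, inclusive) and
    the hydrophobic fraction S_pho/S to a SASA result."""
    charges = np.asarray(charges, dtype=float).reshape(-1)
    if len(charges) != len(sasa.per_atom_area):
        raise ValueError("charges must align with per-atom areas")
    if np.any(np.isnan(charges)):
        raise ValueError("atoms lack partial charges (run assign_parameters)")
    nonpolar = np.abs(charges) <= threshold
    s_pho = float(sasa.per_atom_area[nonpolar].sum())
    frac = s_pho / sasa.total_S if sasa.total_S > 0 else 0.0
    return SASAResult(per_atom_area=sasa.per_atom_area, total_S=sasa.total_S,
                      S_pho=s_pho, fraction_pho=frac)


def selection_sasa(sasa: SASAResult, atom_indices: np.ndarray) -> float:
    """SASA of a selection, in the context of the whole protein (sum of the
    selection atoms' per-atom areas from a whole-protein SASA run)."""
    atom_indices = np.asarray(atom_indices, dtype=int)
    if atom_indices.size == 0:
        raise ValueError("empty selection")
    return float(sasa.per_atom_area[atom_indices].sum())


def surface_water_count(water_ox: np.ndarray, sel_coords: np.ndarray,
                        box: np.ndarray, cutoff: float = 0.55) -> int:
    """Distinct water molecules with oxygen within `cutoff` (minimum image)
    of ANY of the selection's heavy atoms; each water counted once."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if len(water_ox) == 0 or len(sel_coords) == 0:
        return 0
    box = np.asarray(box, dtype=float)
    tree = cKDTree(np.mod(water_ox, box), boxsize=box)
    counted = np.zeros(len(water_ox), dtype=bool)
    for hits in tree.query_ball_point(np.mod(sel_coords, box), r=cutoff):
        counted[hits] = True
    return int(counted.sum())


def sasa_series(traj: Trajectory, probe: float = 0.14,
                n_points: int = 960) -> list[SASAResult]:
    """Whole-protein SASA for every frame (computed once for rigid proteins)."""
    topo = traj.topology
    prot_heavy = topo.is_protein & topo.is_heavy
    radii = topo.vdw_radii[prot_heavy]
    out = []
    first = None
    cached = None
    for fr in traj.frames:
        pc = traj.frame_mask(fr, prot_heavy)
        if cached is not None and pc.shape == first.shape and np.array_equal(pc, first):
            out.append(cached)
            continue
        res = compute_sasa(pc, radii, probe=probe, n_points=n_points)
        if first is None:
            first, cached = pc, res
        out.append(res)
    return out


def surface_density(traj: Trajectory, selection: SurfaceSelection,
                    sasa_per_frame: list[SASAResult], fict_traj: Trajectory,
                    cutoff: float = 0.55, n_blocks: int = 3) -> SurfaceDensityResult:
    """rho_surf, rho_surf_fict and eta_surf for one selection.

    Means of N_w and S are taken separately over frames (ratio of means);
    the fictitious count uses the real protein's SASA series, so eta_surf
    reduces to <N_w>/<N_w_fict> - 1 at equal S.
    """
    topo = traj.topology
    prot_heavy_idx = np.flatnonzero(topo.is_protein & topo.is_heavy)
    sel_idx = selection.atom_indices(topo, heavy_only=True)
    if sel_idx.size == 0:
        raise ValueError(f"selection {selection.label} resolves to no atoms")
    # map selection atoms to positions within the protein-heavy subset
    pos_in_heavy = {int(a): k for k, a in enumerate(prot_heavy_idx)}
    sel_rows = np.array([pos_in_heavy[int(i)] for i in sel_idx])

    def counts(t: Trajectory) -> np.ndarray:
        tp = t.topology
        heavy_mask = tp.is_protein & tp.is_heavy
        out = np.empty(t.n_frames)
        for i, fr in enumerate(t.frames):
            prot = t.frame_mask(fr, heavy_mask)
            ow = t.frame_mask(fr, tp.is_water_oxygen)
            out[i] = surface_water_count(ow, prot[sel_rows], fr.box, cutoff)
        return out

    n_real = counts(traj)
    n_fict = counts(fict_traj)
    s_sel = np.array([selection_sasa(s, sel_rows) for s in sasa_per_frame])

    N_mean, N_se = subtrajectory_errors(n_real, n_blocks)
    Nf_mean, Nf_se = subtrajectory_errors(n_fict, n_blocks)
    S_mean, _ = subtrajectory_errors(s_sel, n_blocks) if len(set(s_sel)) > 1 \
        else (float(s_sel.mean()), 0.0)
    if Nf_mean <= 0:
        raise ValueError("fictitious configurations give zero surface waters")
    rho = N_mean / S_mean
    rho_f = Nf_mean / S_mean
    eta_surf = rho / rho_f - 1.0
    eta_se = (1.0 + eta_surf) * np.sqrt((N_se / N_mean) ** 2 + (Nf_se / Nf_mean) ** 2)
    return SurfaceDensityResult(
        selection_label=selection.label, N_w_mean=N_mean, S_mean=S_mean,
        rho_surf=rho, rho_surf_fict=rho_f, eta_surf=eta_surf,
        errors={"N_w": N_se, "N_w_fict": Nf_se, "eta_surf": float(eta_se)},
    )
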