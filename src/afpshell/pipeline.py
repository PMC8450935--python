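"""Per-protein orchestration and cross-protein summaries.

run_protein drives the full analysis of one protein: parameter assignment,
ellipsoid fit on the superposed trajectory-average structure, density
profiles against the fictitious bulk-overlay reference, whole-shell
metrics, SASA and hydrophobic fractions, and per-surface local densities.
correlate/group_compare quantify the cross-protein trends (density
increment vs partial molar volume; moderate vs hyperactive class means).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .ellipsoid import EllipsoidModel, fit_ellipsoid
from .profiles import (DensityProfile, PlateauResult, RatioProfile,
                       compute_density_profile, detect_plateau,
                       make_fictitious_configs, ratio_profile)
from .reference_data import activity_class
from .shell import RHO_BULK_DEFAULT, ShellSummary, summarize_shell
from .structure_io import (ParameterTable, SurfaceSelection, Trajectory,
                           assign_parameters, default_parameter_table,
                           load_selection, read_structure, read_trajectory)
from .surface import (SASAResult, SurfaceDensityResult, hydrophobic_fraction,
                      sasa_series, selection_sasa, surface_density)

logger = logging.getLogger("afpshell")

__all__ = ["ProteinRunConfig", "ProteinResult", "CorrelationReport",
           "run_protein", "correlate", "group_compare",
           "shell_summary_row", "surface_rows", "write_tsv"]


@dataclass
class ProteinRunConfig:
    """Inputs and parameters for one protein's analysis.

    Trajectories may be given as paths (structure_path + trajectory_path +
    bulk_path) or as in-memory Trajectory objects (trajectory, bulk) —
    synthetic runs use the latter.  delta_T is pass-through metadata used
    only for activity classification.
    """

    name: str = "protein"
    structure_path: str | None = None
    trajectory_path: str | None = None
    bulk_path: str | None = None
    trajectory: Trajectory | None = None
    bulk: Trajectory | None = None
    params: ParameterTable | None = None
    ibs_residues: list | None = None
    delta_T: float | None = None
    shell_thickness: float = 1.0
    surface_cutoff: float = 0.55
    probe: float = 0.14
    charge_threshold: float = 0.2
    rho_bulk: float = RHO_BULK_DEFAULT
    bin_width: float = 0.02
    d_max: float = 2.0
    n_blocks: int = 3
    sasa_points: int = 960
    compute_profile: bool = True

    @property
    def activity_class(self) -> str | None:
        return None if self.delta_T is None else activity_class(self.delta_T)


@dataclass
class ProteinResult:
    name: str
    ellipsoid: EllipsoidModel
    shell: ShellSummary
    sasa_whole: SASAResult                       # with S_pho attached
    selection_areas: dict                        # label -> dict(S, S_pho, fraction)
    surface: dict                                # label -> SurfaceDensityResult
    profile_real: DensityProfile | None = None
    profile_fict: DensityProfile | None = None
    ratio: RatioProfile | None = None
    plateau: PlateauResult | None = None
    delta_T: float | None = None

    @property
    def activity_class(self) -> str | None:
        return None if self.delta_T is None else activity_class(self.delta_T)


@dataclass
class CorrelationReport:
    """Pearson correlation + OLS fit for one (x, y) variable pair."""

    x_name: str
    y_name: str
    n: int
    pearson_r: float
    p_value: float
    slope: float
    intercept: float
    points: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12:
            raise ValueError("|r| must be <= 1")


def _superposed_mean_structure(traj: Trajectory) -> np.ndarray:
    """Trajectory-average protein heavy-atom coordinates after rigid-body
    superposition of every frame onto the first (Kabsch via scipy)."""
    from scipy.spatial.transform import Rotation

    mask = traj.topology.is_protein & traj.topology.is_heavy
    ref = traj.frame_mask(traj.frames[0], mask)
    ref_c = ref - ref.mean(axis=0)
    acc = np.zeros_like(ref)
    for fr in traj.frames:
        pc = traj.frame_mask(fr, mask)
        pc_c = pc - pc.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_c, pc_c)
        acc += rot.apply(pc_c)
    mean = acc / traj.n_frames + ref.mean(axis=0)
    return mean


def run_protein(config: ProteinRunConfig) -> ProteinResult:
    """Run the full single-protein analysis.

    Deterministic given its inputs.  A missing IBS list degrades to a
    whole-protein-only analysis with a warning.
    """
    params = config.params or default_parameter_table()
    if config.trajectory is not None:
        traj = config.trajectory
    else:
        if config.trajectory_path is None:
            raise ValueError(f"[{config.name}] no trajectory given")
        topo = (read_structure(config.structure_path)
                if config.structure_path else None)
        traj = read_trajectory(config.trajectory_path, topo)
    assign_parameters(traj, params)
    if config.bulk is not None:
        bulk = config.bulk
    elif config.bulk_path is not None:
        bulk = read_trajectory(config.bulk_path)
    else:
        raise ValueError(f"[{config.name}] a bulk-water trajectory is required "
                         "for the fictitious reference")
    assign_parameters(bulk, params)

    topo = traj.topology
    mean_heavy = _superposed_mean_structure(traj)
    ellipsoid = fit_ellipsoid(mean_heavy)
    logger.info("[%s] ellipsoid semi-axes %s nm", config.name,
                np.round(ellipsoid.semi_axes, 3))

    fict = make_fictitious_configs(traj, bulk)

    profile_real = profile_fict = ratio = plateau = None
    if config.compute_profile:
        profile_real = compute_density_profile(
            traj, ellipsoid, bin_width=config.bin_width, d_max=config.d_max)
        profile_fict = compute_density_profile(
            fict, ellipsoid, bin_width=config.bin_width, d_max=config.d_max)
        ratio = ratio_profile(profile_real, profile_fict)
        plateau = detect_plateau(ratio)
        if plateau.found:
            logger.info("[%s] bulk plateau from %.2f nm", config.name, plateau.distance)
        else:
            logger.warning("[%s] no bulk plateau found within d_max", config.name)

    shell = summarize_shell(traj, ellipsoid, thickness=config.shell_thickness,
                            rho_bulk=config.rho_bulk, probe=config.probe,
                            n_blocks=config.n_blocks)

    sasa = sasa_series(traj, probe=config.probe, n_points=config.sasa_points)
    prot_heavy_idx = np.flatnonzero(topo.is_protein & topo.is_heavy)
    charges = topo.partial_charges[prot_heavy_idx]
    # frame-averaged whole-protein SASA with hydrophobic split
    mean_areas = np.mean([s.per_atom_area for s in sasa], axis=0)
    whole = hydrophobic_fraction(
        SASAResult(per_atom_area=mean_areas, total_S=float(mean_areas.sum())),
        charges, threshold=config.charge_threshold)

    selections: list[SurfaceSelection] = []
    all_res = frozenset((a.chain_id, a.residue_id) for a in topo if not a.is_water)
    whole_sel = SurfaceSelection("WP", all_res)
    if config.ibs_residues:
        ibs, nibs = load_selection({"ibs_residues": config.ibs_residues}, topo)
        selections = [ibs, nibs, whole_sel]
    else:
        logger.warning("[%s] no IBS residue list: whole-protein analysis only",
                       config.name)
        selections = [whole_sel]

    sel_areas = {}
    surface = {}
    nonpolar = np.abs(charges) <= config.charge_threshold
    pos_in_heavy = {int(a): k for k, a in enumerate(prot_heavy_idx)}
    for sel in selections:
        rows = np.array([pos_in_heavy[int(i)]
                         for i in sel.atom_indices(topo, heavy_only=True)])
        s_sel = float(mean_areas[rows].sum())
        s_pho = float(mean_areas[rows][nonpolar[rows]].sum())
        sel_areas[sel.label] = {"S": s_sel, "S_pho": s_pho,
                                "fraction_pho": s_pho / s_sel if s_sel else 0.0}
        surface[sel.label] = surface_density(
            traj, sel, sasa, fict, cutoff=config.surface_cutoff,
            n_blocks=config.n_blocks)

    return ProteinResult(
        name=config.name, ellipsoid=ellipsoid, shell=shell, sasa_whole=whole,
        selection_areas=sel_areas, surface=surface,
        profile_real=profile_real, profile_fict=profile_fict,
        ratio=ratio, plateau=plateau, delta_T=config.delta_T,
    )


def correlate(points: pd.DataFrame, x: str, y: str,
              classes: pd.Series | None = None) -> CorrelationReport:
    """Pearson r (two-sided p from the t transform) and OLS fit of y on x."""
    if len(points) < 3:
        raise ValueError("need at least 3 points to correlate")
    xv = points[x].to_numpy(dtype=float)
    yv = points[y].to_numpy(dtype=float)
    if np.ptp(xv) == 0:
        raise ValueError(f"zero variance in {x}")
    r, p = stats.pearsonr(xv, yv)
    fit = stats.linregress(xv, yv)
    return CorrelationReport(x_name=x, y_name=y, n=len(points),
                             pearson_r=float(r), p_value=float(p),
                             slope=float(fit.slope), intercept=float(fit.intercept),
                             points=points[[x, y]].copy())


def group_compare(values_by_class: dict) -> dict:
    """Per-class means and their difference (hyperactive - moderate)."""
    means = {}
    for cls, vals in values_by_class.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size == 0:
            raise ValueError(f"empty class {cls!r}")
        means[cls] = float(vals.mean())
    out = {"means": means}
    if {"moderate", "hyperactive"} <= means.keys():
        out["difference"] = means["hyperactive"] - means["moderate"]
    return out


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def shell_summary_row(res: ProteinResult, n_residues: int | None = None) -> dict:
    s = res.shell
    return {
        "protein": res.name,
        "RN": n_residues,
        "delta_T": res.delta_T,
        "V_ex": s.V_ex_mean, "V_ex_err": s.errors.get("V_ex"),
        "V_shell": s.V_shell_mean,
        "N_shell": s.N_shell_mean, "N_shell_err": s.errors.get("N_shell"),
        "rho_shell": s.rho_shell, "rho_bulk": s.rho_bulk,
        "eta": s.eta, "eta_err": s.errors.get("eta"),
        "pmv": s.pmv, "pmv_err": s.errors.get("pmv"),
    }


def surface_rows(res: ProteinResult) -> list[dict]:
    rows = []
    for label, sd in res.surface.items():
        area = res.selection_areas[label]
        rows.append({
            "protein": res.name, "selection": label,
            "S": area["S"], "S_pho": area["S_pho"],
            "fraction_pho": area["fraction_pho"],
            "N_w": sd.N_w_mean, "rho_surf": sd.rho_surf,
            "rho_surf_fict": sd.rho_surf_fict,
            "eta_surf": sd.eta_surf,
            "eta_surf_err": sd.errors.get("eta_surf"),
        })
    return rows


def write_tsv(rows, path) -> None:
    """Write result rows (list of dicts or DataFrame) as TSV."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
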