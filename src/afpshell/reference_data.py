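"""Published per-protein hydration-shell values for eight antifreeze proteins.

These are the printed whole-shell inputs and results (mean excluded volume
V_ex and shell volume V_shell in nm^3, mean shell water count N_shell,
density increment eta, partial molar volume v in l/mol), the surface areas
(S in nm^2) with hydrophobic fractions, and the per-surface density
increments eta_surf for the ice-binding (IBS) and non-ice-binding (NIBS)
surfaces, together with residue counts (RN) and experimental thermal
hysteresis (delta_T, K, at 0.3 g/l).

They serve as cross-check inputs: the package's eta/v arithmetic must
reproduce the printed eta and v from the printed (V_ex, V_shell, N_shell),
and the published surface values drive the correlation and group-comparison
demonstrations without rerunning the underlying simulations.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["shell_table", "surface_area_table", "eta_surf_table",
           "activity_class", "MODERATE", "HYPERACTIVE"]

_SHELL_ROWS = [
    # name, RN, delta_T (K), V_ex, V_shell, N_shell, eta, v
    ("TisAFP6", 222, 0.08, 34.57, 95.58, 2266, 0.114, 16.61),
    ("PaAFP", 37, 0.10, 5.78, 43.71, 1329, 0.051, 2.30),
    ("ZaAFP", 66, 0.18, 11.50, 48.07, 1305, 0.071, 5.35),
    ("TisAFP8", 223, 0.36, 34.46, 95.85, 2254, 0.102, 16.98),
    ("CfAFP337", 87, 1.34, 13.81, 53.16, 1417, 0.081, 6.40),
    ("TmAFP", 82, 2.22, 12.24, 49.87, 1358, 0.082, 5.48),
    ("RiAFP", 139, 3.43, 21.16, 75.82, 1983, 0.089, 9.82),
    ("CfAFP501", 120, 4.28, 19.11, 66.18, 1707, 0.088, 9.01),
]

_SURFACE_AREA_ROWS = [
    # name, S_WP, S_IBS, Spho/S WP, IBS, NIBS
    ("TisAFP6", 99.87, 10.11, 0.56, 0.56, 0.56),
    ("PaAFP", 30.31, 7.60, 0.54, 0.64, 0.51),
    ("ZaAFP", 40.09, 8.17, 0.58, 0.67, 0.56),
    ("TisAFP8", 98.25, 10.70, 0.59, 0.70, 0.57),
    ("CfAFP337", 48.56, 8.02, 0.52, 0.58, 0.51),
    ("TmAFP", 42.68, 7.57, 0.46, 0.61, 0.42),
    ("RiAFP", 72.97, 15.46, 0.52, 0.54, 0.52),
    ("CfAFP501", 62.85, 8.66, 0.49, 0.67, 0.47),
]

_ETA_SURF_ROWS = [
    # name, eta_surf IBS, eta_surf NIBS
    ("TisAFP6", 0.056, 0.057),
    ("PaAFP", 0.033, 0.053),
    ("ZaAFP", 0.038, 0.055),
    ("TisAFP8", 0.032, 0.054),
    ("CfAFP337", 0.052, 0.064),
    ("TmAFP", 0.047, 0.077),
    ("RiAFP", 0.059, 0.063),
    ("CfAFP501", 0.040, 0.069),
]

MODERATE = ("TisAFP6", "PaAFP", "ZaAFP", "TisAFP8")
HYPERACTIVE = ("CfAFP337", "TmAFP", "RiAFP", "CfAFP501")


def shell_table() -> pd.DataFrame:
    return pd.DataFrame(
        _SHELL_ROWS,
        columns=["protein", "RN", "delta_T", "V_ex", "V_shell", "N_shell",
                 "eta", "pmv"],
    ).set_index("protein")


def surface_area_table() -> pd.DataFrame:
    return pd.DataFrame(
        _SURFACE_AREA_ROWS,
        columns=["protein", "S_WP", "S_IBS", "spho_WP", "spho_IBS", "spho_NIBS"],
    ).set_index("protein")


def eta_surf_table() -> pd.DataFrame:
    return pd.DataFrame(
        _ETA_SURF_ROWS,
        columns=["protein", "eta_surf_IBS", "eta_surf_NIBS"],
    ).set_index("protein")


def activity_class(delta_T: float) -> str:
    """Moderate (delta_T < 1 K) vs hyperactive (delta_T > 1 K)."""
    return "moderate" if delta_T < 1.0 else "hyperactive"
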