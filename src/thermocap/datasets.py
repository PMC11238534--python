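"""Published benchmark values for six melagatran-analogue thrombin inhibitors.

Two small reference tables accompany the package:

* ``dudt_table()`` - temperature derivatives of the mean total potential
  energy (kcal/mol/K) from droplet MD of the holoenzyme, apoenzyme,
  ligand-in-water and pure-water systems for inhibitors 2-4, with and
  without the hirugen exosite peptide, together with the published
  calculated and experimental binding dCp values.

* ``equilibrium_table()`` - mandatory-coupling equilibrium parameters
  (kcal/mol, kcal/mol/K) fitted to calorimetric apparent binding enthalpies
  of six inhibitors (ligands 0-5), with the derived 298 K observables.

These are inputs for worked examples, cross-checks and the acceptance
script; nothing in the package is fitted to them at import time.
"""

from __future__ import annotations

import pandas as pd

from .equilibrium import EquilibriumParams

_DUDT_ROWS = [
    # inhibitor, hirugen, d_holo, d_apo, d_lig, d_wat, dcp_calc, dcp_expt
    ("2", False, 66.962, 67.307, 23.083, 22.871, -0.56, -0.41),
    ("2", True, 66.699, 66.857, 23.083, 22.871, -0.37, -0.41),
    ("3", False, 67.191, 67.307, 23.072, 22.871, -0.32, -0.42),
    ("3", True, 66.649, 66.857, 23.072, 22.871, -0.41, -0.42),
    ("4", False, 67.310, 67.307, 23.063, 22.871, -0.19, -0.39),
    ("4", True, 66.829, 66.857, 23.063, 22.871, -0.22, -0.39),
]

_EQUILIBRIUM_ROWS = [
    # ligand, dh_eq, ds_eq, dh_b, ds_b, dh_app_298, dh_exp_298,
    # dg_eq_298, dg_b_298, dg_app_298
    ("0", 17.89, 0.0590, 0.07, 0.0422, -6.64, -6.65, 0.30, -12.50, -12.22),
    ("1", 17.49, 0.0579, 1.86, 0.0467, -5.24, -5.03, 0.23, -12.06, -11.75),
    ("2", 17.63, 0.0583, 2.21, 0.0486, -4.81, -4.55, 0.24, -12.29, -11.99),
    ("3", 17.86, 0.0601, 3.69, 0.0559, -5.57, -5.61, -0.04, -12.97, -12.54),
    ("4", 17.02, 0.0565, 1.70, 0.0491, -5.50, -5.21, 0.18, -12.93, -12.61),
    ("5", 17.50, 0.0575, 1.50, 0.0477, -4.76, -4.55, 0.35, -12.74, -12.47),
]

#: Published alternative (mirror) solution for ligand 5.
ALTERNATIVE_SOLUTION_LIGAND5 = {
    "dh_eq": -17.50,
    "ds_eq": -0.0575,
    "dh_b": -16.00,
    "ds_b": -0.0098,
}


def dudt_table() -> pd.DataFrame:
    """The dU/dT benchmark table (one row per inhibitor/hirugen combination)."""
    return pd.DataFrame(
        _DUDT_ROWS,
        columns=[
            "inhibitor",
            "hirugen",
            "d_holo",
            "d_apo",
            "d_lig",
            "d_wat",
            "delta_cp_calc",
            "delta_cp_expt",
        ],
    )


def equilibrium_table() -> pd.DataFrame:
    """The per-ligand equilibrium-parameter benchmark table."""
    return pd.DataFrame(
        _EQUILIBRIUM_ROWS,
        columns=[
            "ligand",
            "dh_eq",
            "ds_eq",
            "dh_b",
            "ds_b",
            "dh_app_298",
            "dh_exp_298",
            "dg_eq_298",
            "dg_b_298",
            "dg_app_298",
        ],
    )


def equilibrium_params(ligand: str) -> EquilibriumParams:
    """The fitted parameters of one ligand as an :class:`EquilibriumParams`."""
    table = equilibrium_table().set_index("ligand")
    row = table.loc[str(ligand)]
    return EquilibriumParams(
        dh_eq=float(row["dh_eq"]),
        ds_eq=float(row["ds_eq"]),
        dh_b=float(row["dh_b"]),
        ds_b=float(row["ds_b"]),
    )
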