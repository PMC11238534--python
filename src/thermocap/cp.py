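"""Binding heat capacity from temperature derivatives of mean energy.

The estimator exploits that the binding heat-capacity change can be obtained
without free-energy calculations, from the slopes ``dU/dT`` of the mean total
potential energy versus temperature for four systems forming a closed
thermodynamic cycle::

    dCp_bind = (dU/dT|holo - dU/dT|apo) - (dU/dT|lig - dU/dT|wat)

The holo and apo systems (and likewise the ligand-in-water and pure-water
systems) must contain the same number of water molecules so that the cycle
involves no change in the number of degrees of freedom; a residual water-count
imbalance is corrected with the heat capacity of bulk water per molecule.
Kinetic-energy contributions cancel in the cycle and enter only through the
explicit ``3R`` equipartition term when a *per-molecule* total heat capacity
is requested (:func:`per_molecule_cp`).

The module also provides the integrated constant-dCp van't Hoff model

    dG(T) = dH0 - T*dS0 + dCp*[(T - T0) - T*ln(T/T0)]

as the conventional description of a temperature-dependent binding free
energy with constant heat-capacity change.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

from .constants import BULK_WATER_CP, R_KCAL
from .energy import TemperatureScan
from .errors import InsufficientDataError

__all__ = [
    "LinearFit",
    "CpBindingResult",
    "VantHoffParams",
    "VantHoffFit",
    "fit_dudt",
    "binding_heat_capacity",
    "per_molecule_cp",
    "vant_hoff_dg",
    "fit_vant_hoff",
    "HeatCapacityModel",
    "HeatCapacityResults",
]


@dataclass(frozen=True)
class LinearFit:
    """Ordinary least-squares line through a temperature scan.

    ``slope`` is dU/dT in kcal/mol/K, ``slope_se`` its asymptotic standard
    error, ``r_squared`` the conventional coefficient of determination.
    """

    slope: float
    intercept: float
    slope_se: float
    r_squared: float
    n_points: int

    def __post_init__(self):
        if self.slope_se < 0:
            raise ValueError("slope_se must be >= 0")
        if self.n_points < 3:
            raise InsufficientDataError("a dU/dT fit needs >= 3 points")


@dataclass(frozen=True)
class CpBindingResult:
    """The four derivatives and the assembled binding dCp (kcal/mol/K)."""

    d_holo: float
    d_apo: float
    d_lig: float
    d_wat: float
    water_imbalance_correction: float
    delta_cp: float
    delta_cp_se: float

    def __post_init__(self):
        expected = (
            (self.d_holo - self.d_apo)
            - (self.d_lig - self.d_wat)
            + self.water_imbalance_correction
        )
        if self.delta_cp != expected:
            raise ValueError("delta_cp does not satisfy the cycle identity")


@dataclass(frozen=True)
class VantHoffParams:
    """Constant-dCp van't Hoff parameters at reference temperature ``t0``."""

    dh0: float
    ds0: float
    dcp: float
    t0: float

    def __post_init__(self):
        if not self.t0 > 0:
            raise ValueError("reference temperature must be > 0 K")


@dataclass(frozen=True)
class VantHoffFit:
    params: VantHoffParams
    bse: dict
    r_squared: float
    resid: np.ndarray


def _ols(x: np.ndarray, y: np.ndarray) -> LinearFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or np.unique(x).size < 3:
        raise InsufficientDataError(f"need >= 3 distinct x values, got {np.unique(x).size}")
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    slope = float(((x - xm) * (y - ym)).sum() / sxx)
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - ym) ** 2).sum())
    s2 = ss_res / (n - 2)
    slope_se = math.sqrt(s2 / sxx)
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return LinearFit(slope, float(intercept), slope_se, r_squared, n)


def fit_dudt(scan) -> LinearFit:
    """OLS fit of mean energy on temperature.

    ``scan`` is a :class:`~thermocap.energy.TemperatureScan` or a
    ``(temperatures, mean_energies)`` pair of sequences.  The fit is
    unweighted: the per-point block SEMs are diagnostics, not weights.
    """
    if isinstance(scan, TemperatureScan):
        x, y = scan.temperatures, scan.mean_energies
    else:
        x, y = scan
    return _ols(np.asarray(x, float), np.asarray(y, float))


def _slope_and_se(fit) -> tuple[float, float]:
    if isinstance(fit, LinearFit):
        return fit.slope, fit.slope_se
    return float(fit), 0.0


def binding_heat_capacity(
    holo,
    apo,
    lig,
    wat,
    n_water_imbalance: int = 0,
    per_water_cp: float = BULK_WATER_CP,
) -> CpBindingResult:
    """Combine the four dU/dT derivatives into the binding dCp.

    Each of ``holo``/``apo``/``lig``/``wat`` is a :class:`LinearFit` or a bare
    slope in kcal/mol/K (bare slopes carry zero standard error).
    ``n_water_imbalance`` is the number of waters in the holo system minus the
    apo system; the correction ``-n_water_imbalance * per_water_cp`` restores
    the equal-degrees-of-freedom bookkeeping of the cycle.  The dCp standard
    error is the quadrature sum of the four slope SEs.
    """
    d_holo, se_holo = _slope_and_se(holo)
    d_apo, se_apo = _slope_and_se(apo)
    d_lig, se_lig = _slope_and_se(lig)
    d_wat, se_wat = _slope_and_se(wat)
    correction = -n_water_imbalance * per_water_cp
    delta_cp = (d_holo - d_apo) - (d_lig - d_wat) + correction
    delta_cp_se = math.sqrt(se_holo**2 + se_apo**2 + se_lig**2 + se_wat**2)
    return CpBindingResult(
        d_holo, d_apo, d_lig, d_wat, correction, delta_cp, delta_cp_se
    )


def per_molecule_cp(wat, n_molecules: int) -> float:
    """Total heat capacity per molecule of a pure-solvent simulation.

    Adds the ``3R`` kinetic equipartition term to the potential-energy slope
    divided by the number of molecules (the slope tracks potential energy
    only).  For bulk water this lands at the experimental ~0.018 kcal/mol/K.
    """
    if n_molecules <= 0:
        raise ValueError(f"n_molecules must be positive, got {n_molecules}")
    slope, _ = _slope_and_se(wat)
    return slope / n_molecules + 3.0 * R_KCAL


def _vant_hoff_basis(t: np.ndarray, t0: float) -> np.ndarray:
    return (t - t0) - t * np.log(t / t0)


def vant_hoff_dg(params: VantHoffParams, t):
    """dG(T) under the constant-dCp Gibbs-Helmholtz integration.

    Satisfies ``d2(dG)/dT2 = -dCp/T`` (equivalently dCp = -T d2G/dT2).
    Accepts scalar or array ``t`` (kelvin, > 0).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperature must be > 0 K")
    out = params.dh0 - t * params.ds0 + params.dcp * _vant_hoff_basis(t, params.t0)
    return float(out) if out.ndim == 0 else out


def fit_vant_hoff(points, t0: float, fix_dcp: float | None = None) -> VantHoffFit:
    """Least-squares fit of the constant-dCp van't Hoff model to dG(T) data.

    The model is linear in (dH0, dS0, dCp), so the fit is an exact linear
    least-squares solve with asymptotic parameter SEs from the unscaled
    covariance times the residual variance.  ``fix_dcp`` pins the curvature
    term (e.g. at 0 for a plain linear van't Hoff fit), in which case three
    points suffice; otherwise at least four are required.

    Parameters
    ----------
    points : sequence of (temperature_K, dG_kcal_per_mol)
    t0 : float
        Reference temperature for the reported dH0/dS0.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be a sequence of (T, dG) pairs")
    t, g = pts[:, 0], pts[:, 1]
    n_free = 2 if fix_dcp is not None else 3
    n_min = n_free + 1 if fix_dcp is None else 3
    if np.unique(t).size < n_min:
        raise InsufficientDataError(
            f"need >= {n_min} distinct temperatures, got {np.unique(t).size}"
        )
    if np.any(t <= 0):
        raise ValueError("temperatures must be > 0 K")

    curvature = _vant_hoff_basis(t, t0)
    if fix_dcp is not None:
        design = np.column_stack([np.ones_like(t), -t])
        target = g - fix_dcp * curvature
    else:
        design = np.column_stack([np.ones_like(t), -t, curvature])
        target = g

    beta, *_ = np.linalg.lstsq(design, target, rcond=None)
    resid = target - design @ beta
    dof = t.size - design.shape[1]
    s2 = float((resid**2).sum() / dof) if dof > 0 else 0.0
    cov = s2 * np.linalg.pinv(design.T @ design)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    if fix_dcp is not None:
        params = VantHoffParams(float(beta[0]), float(beta[1]), float(fix_dcp), t0)
        bse = {"dh0": float(se[0]), "ds0": float(se[1]), "dcp": 0.0}
    else:
        params = VantHoffParams(float(beta[0]), float(beta[1]), float(beta[2]), t0)
        bse = {"dh0": float(se[0]), "ds0": float(se[1]), "dcp": float(se[2])}
    ss_tot = float(((g - g.mean()) ** 2).sum())
    r_squared = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return VantHoffFit(params, bse, r_squared, resid)


# ---------------------------------------------------------------------------
# Model / Results front end


_SYSTEM_ALIASES = {
    "holo": "holo",
    "apo": "apo",
    "lig": "lig",
    "ligand": "lig",
    "wat": "wat",
    "water": "wat",
}


def canonical_system(label: str) -> str:
    """Map a free-form system label onto holo/apo/lig/wat."""
    head = re.split(r"[:/\s_-]", label.strip().lower(), maxsplit=1)[0]
    if head not in _SYSTEM_ALIASES:
        raise KeyError(f"cannot map system label {label!r} onto holo/apo/lig/wat")
    return _SYSTEM_ALIASES[head]


class HeatCapacityModel:
    """Four-system estimator of the binding heat-capacity change.

    Built from one :class:`~thermocap.energy.TemperatureScan` per leg of the
    cycle.  ``fit()`` performs the four OLS dU/dT fits and assembles the
    binding dCp with quadrature error propagation.

    Examples
    --------
    >>> model = HeatCapacityModel(holo_scan, apo_scan, lig_scan, wat_scan)
    >>> res = model.fit()
    >>> res.delta_cp, res.delta_cp_se       # doctest: +SKIP
    """

    def __init__(
        self,
        holo: TemperatureScan,
        apo: TemperatureScan,
        lig: TemperatureScan,
        wat: TemperatureScan,
        *,
        n_water_imbalance: int = 0,
        per_water_cp: float = BULK_WATER_CP,
        expt_delta_cp: float | None = None,
    ):
        self.scans = {"holo": holo, "apo": apo, "lig": lig, "wat": wat}
        self.n_water_imbalance = n_water_imbalance
        self.per_water_cp = per_water_cp
        self.expt_delta_cp = expt_delta_cp

    @classmethod
    def from_traces(
        cls,
        traces,
        equilibration_fraction: float = 0.0,
        block_count: int = 10,
        **kwargs,
    ) -> "HeatCapacityModel":
        """Group raw traces by canonical system label and aggregate them."""
        from .energy import aggregate_scan

        grouped: dict[str, list] = {"holo": [], "apo": [], "lig": [], "wat": []}
        for trace in traces:
            grouped[canonical_system(trace.system_label)].append(trace)
        missing = [k for k, v in grouped.items() if not v]
        if missing:
            raise InsufficientDataError(f"no traces for system(s): {missing}")
        scans = {
            key: aggregate_scan(val, equilibration_fraction, block_count)
            for key, val in grouped.items()
        }
        return cls(scans["holo"], scans["apo"], scans["lig"], scans["wat"], **kwargs)

    def fit(self) -> "HeatCapacityResults":
        fits = {key: fit_dudt(scan) for key, scan in self.scans.items()}
        cp = binding_heat_capacity(
            fits["holo"],
            fits["apo"],
            fits["lig"],
            fits["wat"],
            n_water_imbalance=self.n_water_imbalance,
            per_water_cp=self.per_water_cp,
        )
        return HeatCapacityResults(self, fits, cp)


class HeatCapacityResults:
    """Results of :meth:`HeatCapacityModel.fit`."""

    def __init__(self, model: HeatCapacityModel, fits: dict, cp: CpBindingResult):
        self.model = model
        self.fits = fits
        self.cp = cp

    @property
    def delta_cp(self) -> float:
        return self.cp.delta_cp

    @property
    def delta_cp_se(self) -> float:
        return self.cp.delta_cp_se

    def to_frame(self):
        """Per-system fit table as a pandas DataFrame."""
        import pandas as pd

        rows = [
            {
                "system": key,
                "dudt_kcal_per_mol_K": fit.slope,
                "dudt_se_kcal_per_mol_K": fit.slope_se,
                "intercept_kcal_per_mol": fit.intercept,
                "r_squared": fit.r_squared,
                "n_points": fit.n_points,
            }
            for key, fit in self.fits.items()
        ]
        return pd.DataFrame(rows).set_index("system")

    def summary(self) -> str:
        lines = ["Binding heat capacity (four-system dU/dT estimator)", ""]
        lines.append(
            f"{'system':<6} {'dU/dT':>10} {'se':>9} {'R^2':>10} {'n':>3}"
        )
        for key in ("holo", "apo", "lig", "wat"):
            fit = self.fits[key]
            lines.append(
                f"{key:<6} {fit.slope:>10.3f} {fit.slope_se:>9.4f} "
                f"{fit.r_squared:>10.6f} {fit.n_points:>3d}"
            )
        lines.append("")
        lines.append(
            f"water imbalance correction: {self.cp.water_imbalance_correction:+.4f} kcal/mol/K"
        )
        lines.append(
            f"delta_Cp = {self.delta_cp:+.3f} +/- {self.delta_cp_se:.3f} kcal/mol/K"
        )
        if self.model.expt_delta_cp is not None:
            lines.append(
                f"experimental reference: {self.model.expt_delta_cp:+.3f} kcal/mol/K"
            )
        return "\n".join(lines)

    def plot_scans(self, ax=None):
        """Plot the four scans and fitted lines (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for key, scan in self.model.scans.items():
            fit = self.fits[key]
            t = scan.temperatures
            ax.errorbar(t, scan.mean_energies, yerr=scan.sems, fmt="o", label=key)
            ax.plot(t, fit.intercept + fit.slope * t, "-", alpha=0.6)
        ax.set_xlabel("temperature (K)")
        ax.set_ylabel("<U> (kcal/mol)")
        ax.legend()
        return ax
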