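"""Mandatory-coupling conformational equilibrium model for binding data.

Scheme::

    (E + L)' <==[K_eq]== E + L ==[K_b]==> EL

Only the binding-competent state ``E + L`` can form the complex ("mandatory
coupling"); ``(E + L)'`` is an inactive conformer of the free enzyme or, as
for the thrombin inhibitors this model was developed around, of the free
ligand (an extended conformation that cannot enter the active site).  With

    K_eq(T) = exp(-(dH_eq - T*dS_eq) / (R*T))

the observables of a calorimetric titration become

    dH_app(T)  = dH_b - dH_eq * K_eq/(1 + K_eq)
    dCp_app(T) = -(dH_eq^2/(R*T^2)) * [1/(1+K_eq)] * [K_eq/(1+K_eq)]
    dG_app(T)  = (dH_b - T*dS_b) + R*T*ln(1 + K_eq)

i.e. a two-state equilibrium with a sizeable dH_eq produces an apparently
negative, nearly constant binding heat capacity over a typical experimental
window without any intrinsic Cp difference between bound and free states.
dCp_app is exactly the temperature derivative of dH_app.

The dH_app model always admits two parameter solutions related by

    dH_eq' = -dH_eq,  dS_eq' = -dS_eq,
    dH_b'  = dH_b - dH_eq,  dS_b' = dS_b - dS_eq

under which every observable is unchanged; :func:`alternate_solution`
switches between them.  Fits report the branch with ``dH_eq > 0`` (inactive
state uphill at low temperature), which the structural analysis of the free
ligands supports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .constants import R_KCAL, T_REF
from .errors import FitError, InsufficientDataError

__all__ = [
    "EquilibriumParams",
    "ITCSeries",
    "keq",
    "apparent_enthalpy",
    "apparent_cp",
    "apparent_free_energy",
    "alternate_solution",
    "EquilibriumModel",
    "EquilibriumResults",
    "fit_equilibrium",
    "summarize_equilibrium",
]


@dataclass(frozen=True)
class EquilibriumParams:
    """Thermodynamic parameters of the mandatory-coupling scheme.

    ``dh_eq``/``ds_eq`` describe the active -> inactive equilibrium,
    ``dh_b``/``ds_b`` the true (binding-competent) binding step.  Units
    kcal/mol and kcal/mol/K.  ``ds_b`` may be NaN when no affinity reference
    was available to pin it.
    """

    dh_eq: float
    ds_eq: float
    dh_b: float
    ds_b: float = math.nan

    def __post_init__(self):
        for name in ("dh_eq", "ds_eq", "dh_b"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def delta_g_eq(self, t):
        return self.dh_eq - np.asarray(t, float) * self.ds_eq

    def delta_g_b(self, t):
        return self.dh_b - np.asarray(t, float) * self.ds_b


@dataclass
class ITCSeries:
    """Apparent binding enthalpies versus temperature, ITC style."""

    temperatures: np.ndarray
    dh_app: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.dh_app = np.asarray(self.dh_app, dtype=float)
        if self.temperatures.shape != self.dh_app.shape:
            raise ValueError("temperatures and dh_app must have the same shape")
        if np.any(self.temperatures <= 0):
            raise ValueError("temperatures must be > 0 K")
        if np.unique(self.temperatures).size != self.temperatures.size:
            raise ValueError("temperatures must be distinct")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.dh_app.shape:
                raise ValueError("sd must match dh_app in shape")
            if np.any(self.sd <= 0):
                raise ValueError("sd values must be positive")

    def __len__(self) -> int:
        return int(self.temperatures.size)

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            cols = "temperature_K,dH_app_kcal_per_mol"
            if self.sd is not None:
                cols += ",sd_kcal_per_mol"
            handle.write(cols + "\n")
            for i in range(len(self)):
                row = f"{float(self.temperatures[i])!r},{float(self.dh_app[i])!r}"
                if self.sd is not None:
                    row += f",{float(self.sd[i])!r}"
                handle.write(row + "\n")

    @classmethod
    def read(cls, path) -> "ITCSeries":
        import pandas as pd

        frame = pd.read_csv(path, comment="#")
        sd = frame["sd_kcal_per_mol"].to_numpy() if "sd_kcal_per_mol" in frame else None
        return cls(
            frame["temperature_K"].to_numpy(),
            frame["dH_app_kcal_per_mol"].to_numpy(),
            sd,
        )


def _check_temperature(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperature must be > 0 K")
    return t


def keq(params: EquilibriumParams, t):
    """Equilibrium constant [inactive]/[active] at temperature ``t``."""
    t = _check_temperature(t)
    out = np.exp(-(params.dh_eq - t * params.ds_eq) / (R_KCAL * t))
    return float(out) if out.ndim == 0 else out


def _inactive_fraction(params: EquilibriumParams, t: np.ndarray) -> np.ndarray:
    # K/(1+K) written as a logistic of -dG_eq/RT for overflow safety
    return expit(-(params.dh_eq - t * params.ds_eq) / (R_KCAL * t))


def apparent_enthalpy(params: EquilibriumParams, t):
    """dH_app(T): true binding enthalpy minus dH_eq times the inactive population."""
    t = _check_temperature(t)
    out = params.dh_b - params.dh_eq * _inactive_fraction(params, t)
    return float(out) if out.ndim == 0 else out


def apparent_cp(params: EquilibriumParams, t):
    """dCp_app(T), the exact temperature derivative of :func:`apparent_enthalpy`.

    Equals ``-(dH_eq^2 / (R T^2)) * p_active * p_inactive``; its magnitude
    peaks at the transition temperature (populations 1/2 each) at
    ``dH_eq^2 / (4 R T^2)``.
    """
    t = _check_temperature(t)
    p_inactive = _inactive_fraction(params, t)
    out = -(params.dh_eq**2 / (R_KCAL * t**2)) * (1.0 - p_inactive) * p_inactive
    return float(out) if out.ndim == 0 else out


def apparent_free_energy(params: EquilibriumParams, t):
    """dG_app(T) = dG_b + RT ln(1 + K_eq), the observable binding free energy.

    The logarithmic term is the penalty for depleting the inactive state.
    Requires a defined ``ds_b``.
    """
    t = _check_temperature(t)
    log_k = -(params.dh_eq - t * params.ds_eq) / (R_KCAL * t)
    ln1p_k = np.logaddexp(0.0, log_k)
    out = params.dh_b - t * params.ds_b + R_KCAL * t * ln1p_k
    return float(out) if out.ndim == 0 else out


def alternate_solution(params: EquilibriumParams) -> EquilibriumParams:
    """The mirror parameter solution producing identical observables."""
    return EquilibriumParams(
        dh_eq=-params.dh_eq,
        ds_eq=-params.ds_eq,
        dh_b=params.dh_b - params.dh_eq,
        ds_b=params.ds_b - params.ds_eq,
    )


# ---------------------------------------------------------------------------
# Fitting


def _solve_ds_b(dh_eq, ds_eq, dh_b, t_ref, dg_app_ref) -> float:
    log_k = -(dh_eq - t_ref * ds_eq) / (R_KCAL * t_ref)
    dg_b = dg_app_ref - R_KCAL * t_ref * np.logaddexp(0.0, log_k)
    return float((dh_b - dg_b) / t_ref)


class EquilibriumModel:
    """Fit the mandatory-coupling model to an ITC enthalpy series.

    Three parameters (dh_eq, ds_eq, dh_b) are estimated from dH_app(T) by
    nonlinear least squares; ds_b is not identified by enthalpies alone and
    is solved from one reference apparent binding free energy when
    ``dg_app_ref=(T_ref, dG_app)`` is supplied, otherwise left NaN and
    flagged in the results.

    The objective has two mirror minima (see module docstring) plus flat
    directions when the equilibrium transition temperature falls outside the
    data range, so the fit multistarts from dh_eq in {5, 10, 20, 40} kcal/mol
    with ds_eq = dh_eq/300 and dh_b at the mean observed enthalpy, keeping
    the solution with the smallest residual sum of squares.  Points are
    weighted by 1/sd^2 when uncertainties are given.
    """

    _DEFAULT_STARTS = (5.0, 10.0, 20.0, 40.0)

    def __init__(self, data: ITCSeries, *, dg_app_ref: tuple[float, float] | None = None):
        self.data = data
        self.dg_app_ref = dg_app_ref

    def _residuals(self, theta: np.ndarray, t: np.ndarray, y: np.ndarray, w: np.ndarray):
        params = EquilibriumParams(theta[0], theta[1], theta[2])
        return (apparent_enthalpy(params, t) - y) * w

    def fit(self, branch: str = "positive", starts=None) -> "EquilibriumResults":
        data = self.data
        if len(data) < 3:
            raise InsufficientDataError(
                f"fitting 3 parameters needs >= 3 points, got {len(data)}"
            )
        if branch not in ("positive", "negative"):
            raise ValueError("branch must be 'positive' or 'negative'")
        t = data.temperatures
        y = data.dh_app
        w = 1.0 / data.sd if data.sd is not None else np.ones_like(y)

        best = None
        start_dh_eqs = starts if starts is not None else self._DEFAULT_STARTS
        for dh_eq0 in start_dh_eqs:
            theta0 = np.array([dh_eq0, dh_eq0 / 300.0, float(y.mean())])
            sol = least_squares(
                self._residuals,
                theta0,
                args=(t, y, w),
                method="lm",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=5000,
            )
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not np.all(np.isfinite(best.x)):
            residual = float(2 * best.cost) if best is not None else math.nan
            raise FitError("equilibrium fit failed to converge", residual=residual)

        theta = best.x
        rss = float(2.0 * best.cost)
        dof = len(data) - 3
        s2 = rss / dof if dof > 0 else math.nan
        jtj_inv = np.linalg.pinv(best.jac.T @ best.jac)
        cov = s2 * jtj_inv if dof > 0 else np.full((3, 3), math.nan)

        flip = (branch == "positive" and theta[0] < 0) or (
            branch == "negative" and theta[0] > 0
        )
        if flip:
            transform = np.array([[-1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [-1.0, 0.0, 1.0]])
            theta = transform @ theta
            cov = transform @ cov @ transform.T

        ds_b = math.nan
        ds_b_source = "undefined"
        if self.dg_app_ref is not None:
            t_ref, dg_ref = self.dg_app_ref
            ds_b = _solve_ds_b(theta[0], theta[1], theta[2], t_ref, dg_ref)
            ds_b_source = "reference"
        params = EquilibriumParams(float(theta[0]), float(theta[1]), float(theta[2]), ds_b)

        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        bse = {
            "dh_eq": float(se[0]),
            "ds_eq": float(se[1]),
            "dh_b": float(se[2]),
            "ds_b": math.nan,
        }
        resid = apparent_enthalpy(params, t) - y
        return EquilibriumResults(
            model=self,
            params=params,
            bse=bse,
            cov=cov,
            resid=resid,
            rss=rss,
            n_obs=len(data),
            converged=bool(best.success),
            branch=branch,
            ds_b_source=ds_b_source,
        )


class EquilibriumResults:
    """Results of :meth:`EquilibriumModel.fit`."""

    def __init__(
        self, model, params, bse, cov, resid, rss, n_obs, converged, branch, ds_b_source
    ):
        self.model = model
        self.params = params
        self.bse = bse
        self.cov = cov
        self.resid = resid
        self.rss = rss
        self.n_obs = n_obs
        self.converged = converged
        self.branch = branch
        self.ds_b_source = ds_b_source

    def predict_enthalpy(self, t):
        return apparent_enthalpy(self.params, t)

    def predict_cp(self, t):
        return apparent_cp(self.params, t)

    def predict_free_energy(self, t):
        return apparent_free_energy(self.params, t)

    def alternate(self) -> "EquilibriumResults":
        """Same fit expressed in the mirror parameter solution."""
        transform = np.array([[-1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [-1.0, 0.0, 1.0]])
        cov = transform @ self.cov @ transform.T
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        bse = {
            "dh_eq": float(se[0]),
            "ds_eq": float(se[1]),
            "dh_b": float(se[2]),
            "ds_b": math.nan,
        }
        return EquilibriumResults(
            model=self.model,
            params=alternate_solution(self.params),
            bse=bse,
            cov=cov,
            resid=self.resid,
            rss=self.rss,
            n_obs=self.n_obs,
            converged=self.converged,
            branch="negative" if self.branch == "positive" else "positive",
            ds_b_source=self.ds_b_source,
        )

    def derived_row(self, t_ref: float = T_REF) -> dict:
        """Derived observables at the reference temperature (kcal/mol)."""
        p = self.params
        row = {
            "dh_eq": p.dh_eq,
            "ds_eq": p.ds_eq,
            "dh_b": p.dh_b,
            "ds_b": p.ds_b,
            "dh_app_ref": apparent_enthalpy(p, t_ref),
            "dg_eq_ref": float(p.delta_g_eq(t_ref)),
            "dcp_app_ref": apparent_cp(p, t_ref),
        }
        if math.isfinite(p.ds_b):
            row["dg_b_ref"] = float(p.delta_g_b(t_ref))
            row["dg_app_ref"] = apparent_free_energy(p, t_ref)
        else:
            row["dg_b_ref"] = math.nan
            row["dg_app_ref"] = math.nan
        return row

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([self.derived_row()])

    def summary(self, t_ref: float = T_REF) -> str:
        p = self.params
        row = self.derived_row(t_ref)
        lines = [
            "Mandatory-coupling equilibrium fit to dH_app(T)",
            f"  n = {self.n_obs}, rss = {self.rss:.6g} kcal^2/mol^2, "
            f"branch = {self.branch}, converged = {self.converged}",
            "",
            f"  dH_eq = {p.dh_eq:9.3f} +/- {self.bse['dh_eq']:.3f} kcal/mol",
            f"  dS_eq = {p.ds_eq:9.5f} +/- {self.bse['ds_eq']:.5f} kcal/mol/K",
            f"  dH_b  = {p.dh_b:9.3f} +/- {self.bse['dh_b']:.3f} kcal/mol",
        ]
        if math.isfinite(p.ds_b):
            lines.append(f"  dS_b  = {p.ds_b:9.5f} kcal/mol/K (from {self.ds_b_source})")
        else:
            lines.append("  dS_b  : undefined (no dG_app reference supplied)")
        lines += [
            "",
            f"  at T = {t_ref:.2f} K:",
            f"    dH_app  = {row['dh_app_ref']:8.3f} kcal/mol",
            f"    dG_eq   = {row['dg_eq_ref']:8.3f} kcal/mol",
            f"    dCp_app = {row['dcp_app_ref']:8.4f} kcal/mol/K",
        ]
        if math.isfinite(p.ds_b):
            lines.append(f"    dG_b    = {row['dg_b_ref']:8.3f} kcal/mol")
            lines.append(f"    dG_app  = {row['dg_app_ref']:8.3f} kcal/mol")
        return "\n".join(lines)

    def plot(self, ax=None, t_grid=None):
        """Data and fitted dH_app(T) curve (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        data = self.model.data
        if data.sd is not None:
            ax.errorbar(data.temperatures, data.dh_app, yerr=data.sd, fmt="ks")
        else:
            ax.plot(data.temperatures, data.dh_app, "ks")
        if t_grid is None:
            t_grid = np.linspace(data.temperatures.min() - 5, data.temperatures.max() + 5, 200)
        ax.plot(t_grid, self.predict_enthalpy(t_grid), "b-")
        ax.set_xlabel("temperature (K)")
        ax.set_ylabel("dH_app (kcal/mol)")
        return ax


def fit_equilibrium(
    data: ITCSeries,
    dg_app_ref: tuple[float, float] | None = None,
    branch: str = "positive",
    starts=None,
) -> EquilibriumResults:
    """Functional front end for :class:`EquilibriumModel` (see its docstring)."""
    return EquilibriumModel(data, dg_app_ref=dg_app_ref).fit(branch=branch, starts=starts)


def summarize_equilibrium(params_list) -> "pd.DataFrame":  # noqa: F821
    """Mean and s.e.m. of each parameter over a set of fitted ligands.

    Mirrors the usual per-ligand parameter table summary: the spread of
    dh_eq/ds_eq across ligands is the evidence that a common equilibrium
    underlies the shared dCp.
    """
    import pandas as pd

    frame = pd.DataFrame(
        [
            {"dh_eq": p.dh_eq, "ds_eq": p.ds_eq, "dh_b": p.dh_b, "ds_b": p.ds_b}
            for p in params_list
        ]
    )
    n = len(frame)
    return pd.DataFrame(
        {"mean": frame.mean(), "sem": frame.std(ddof=1) / math.sqrt(n)}
    )
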