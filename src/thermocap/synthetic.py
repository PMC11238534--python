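"""Synthetic-data generators emulating the statistical structure of MD output.

The heat-capacity pipeline is designed around four kinds of input that would
normally come from long droplet MD simulations and from calorimetry:

* energy scans: per-frame total potential energies at several temperatures
  for holo/apo/ligand/water systems, perfectly linear in T on average with
  autocorrelated (AR(1)) noise, so block averaging is non-trivial;
* ITC series: apparent binding enthalpies versus temperature drawn from the
  mandatory-coupling model plus Gaussian noise;
* two-state ligand trajectories: end-to-end distances drawn from a compact
  (~5.5 +/- 0.7 A) and an extended (~12.5 +/- 1.8 A) Gaussian state with
  temperature-dependent populations, plus intramolecular energies trending
  down and ligand-water energies trending up with distance;
* coordinate ensembles: a base structure plus per-residue isotropic Gaussian
  displacements, optionally wrapped in random rigid-body motions to exercise
  superposition.

Every generator is a pure, bit-reproducible function of its spec and a seed.
These generators reproduce the *statistical* structure of the real data
(linearity, bimodality, fluctuation magnitudes), not force-field physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .constants import DEFAULT_SCAN_TEMPERATURES
from .conformations import CoordinateEnsemble
from .energy import EnergyTrace, aggregate_scan, write_energy_table
from .equilibrium import EquilibriumParams, ITCSeries, apparent_enthalpy, keq

__all__ = [
    "ScanSpec",
    "TwoStateSpec",
    "EnergyScanSet",
    "TwoStateTrajectory",
    "gen_energy_scan",
    "gen_itc_series",
    "gen_two_state_trajectory",
    "gen_ensemble",
    "gen_base_structure",
]

SYSTEM_ORDER = ("holo", "apo", "lig", "wat")

#: dU/dT slopes (kcal/mol/K) of a realistic thrombin-inhibitor regime:
#: holo/apo droplets near 67, ligand-in-water/pure-water spheres near 23,
#: combining to a binding dCp of about -0.56 kcal/mol/K.
DEFAULT_SLOPES = {"holo": 66.962, "apo": 67.307, "lig": 23.083, "wat": 22.871}

#: Arbitrary but realistic intercepts for 70 A (protein) / 35 A (water-only)
#: droplet total potential energies.
DEFAULT_INTERCEPTS = {"holo": -95000.0, "apo": -94800.0, "lig": -33500.0, "wat": -33200.0}


@dataclass
class ScanSpec:
    """Generating process for a four-system energy scan.

    ``noise_sd`` is the stationary standard deviation of the AR(1) noise per
    frame (kcal/mol); ``ar1`` its lag-1 coefficient (0.9 by default, making
    naive SEMs visibly overconfident).  Five temperatures spanning 283-303 K
    and five replicas per temperature mirror the usual simulation design.
    """

    slopes: dict = field(default_factory=lambda: dict(DEFAULT_SLOPES))
    intercepts: dict = field(default_factory=lambda: dict(DEFAULT_INTERCEPTS))
    temperatures: tuple = DEFAULT_SCAN_TEMPERATURES
    frames: int = 1000
    replicas: int = 5
    noise_sd: float = 1.0
    ar1: float = 0.9
    frame_interval_ps: float = 1.0

    def __post_init__(self):
        if len(set(self.temperatures)) != len(self.temperatures):
            raise ValueError("temperatures must be distinct")
        if not 0.0 <= self.ar1 < 1.0:
            raise ValueError("AR(1) coefficient must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        missing = [s for s in SYSTEM_ORDER if s not in self.slopes or s not in self.intercepts]
        if missing:
            raise ValueError(f"slopes/intercepts missing for systems: {missing}")

    @property
    def true_delta_cp(self) -> float:
        s = self.slopes
        return (s["holo"] - s["apo"]) - (s["lig"] - s["wat"])


@dataclass
class EnergyScanSet:
    """Output of :func:`gen_energy_scan`: traces per system plus the truth."""

    spec: ScanSpec
    traces: dict

    @property
    def true_delta_cp(self) -> float:
        return self.spec.true_delta_cp

    def scans(self, equilibration_fraction: float = 0.0, block_count: int = 10) -> dict:
        """Aggregate each system's traces into a :class:`TemperatureScan`."""
        return {
            label: aggregate_scan(traces, equilibration_fraction, block_count)
            for label, traces in self.traces.items()
        }

    def write(self, directory) -> dict:
        """One energy-table file per system; returns label -> path."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for label, traces in self.traces.items():
            path = directory / f"energies_{label}.tsv"
            write_energy_table(traces, path)
            paths[label] = path
        return paths


def _ar1_series(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    x0 = rng.normal(0.0, sd)
    innovations = rng.normal(0.0, sd * np.sqrt(1.0 - phi**2), n)
    series, _ = lfilter([1.0], [1.0, -phi], innovations, zi=[phi * x0])
    return series


def gen_energy_scan(spec: ScanSpec, seed: int) -> EnergyScanSet:
    """Generate the four-system energy scan described by ``spec``.

    Per system, temperature and replica the series is
    ``U_t = intercept + slope * T + AR(1) noise``; deterministic under a
    fixed seed.
    """
    rng = np.random.default_rng(seed)
    traces: dict[str, list[EnergyTrace]] = {}
    for label in SYSTEM_ORDER:
        slope = spec.slopes[label]
        intercept = spec.intercepts[label]
        system_traces = []
        for temp in spec.temperatures:
            for rep in range(spec.replicas):
                noise = _ar1_series(rng, spec.frames, spec.ar1, spec.noise_sd)
                system_traces.append(
                    EnergyTrace(
                        system_label=label,
                        temperature=float(temp),
                        replica_id=rep,
                        energies=intercept + slope * temp + noise,
                        frame_interval=spec.frame_interval_ps,
                    )
                )
        traces[label] = system_traces
    return EnergyScanSet(spec, traces)


def gen_itc_series(
    params: EquilibriumParams,
    temperatures=None,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> ITCSeries:
    """Apparent-enthalpy series from the mandatory-coupling model plus noise.

    Defaults to nine temperatures spanning 283-313 K, slightly wider than a
    typical ITC window, which helps pin the equilibrium transition.
    """
    if temperatures is None:
        temperatures = np.linspace(283.0, 313.0, 9)
    temperatures = np.asarray(temperatures, dtype=float)
    rng = np.random.default_rng(seed)
    truth = apparent_enthalpy(params, temperatures)
    noise = rng.normal(0.0, noise_sd, temperatures.size) if noise_sd > 0 else 0.0
    sd = np.full(temperatures.size, noise_sd) if noise_sd > 0 else None
    return ITCSeries(temperatures, truth + noise, sd)


#: Average equilibrium parameters of the six-thrombin-inhibitor benchmark,
#: used as the default two-state generating process.
DEFAULT_TWO_STATE_EQUILIBRIUM = EquilibriumParams(dh_eq=17.57, ds_eq=0.0582, dh_b=0.0, ds_b=0.0)


@dataclass
class TwoStateSpec:
    """Generating process for a compact/extended two-state ligand trajectory.

    The inactive (extended) population is ``K_eq/(1+K_eq)`` from
    ``equilibrium`` at the requested temperature, unless a direct
    ``inactive_fraction`` overrides it.  Energy trends are stylised linear
    relations in the end-to-end distance: the intramolecular energy falls
    (charge-charge repulsion relaxes as the molecule opens) while the
    ligand-water energy rises (weaker solvation of separated charges).
    """

    equilibrium: EquilibriumParams | None = None
    inactive_fraction: float | None = None
    compact_mean: float = 5.5
    compact_sd: float = 0.7
    extended_mean: float = 12.5
    extended_sd: float = 1.8
    intra_slope: float = -2.5
    intra_intercept: float = 8.0
    solvent_slope: float = 3.5
    solvent_intercept: float = -110.0
    energy_noise_sd: float = 3.0
    frames: int = 10000

    def __post_init__(self):
        if not self.compact_mean < self.extended_mean:
            raise ValueError("compact_mean must be below extended_mean")
        if self.compact_sd <= 0 or self.extended_sd <= 0:
            raise ValueError("state standard deviations must be positive")
        if self.inactive_fraction is not None and not 0.0 <= self.inactive_fraction <= 1.0:
            raise ValueError("inactive_fraction must be in [0, 1]")
        if self.equilibrium is None and self.inactive_fraction is None:
            self.equilibrium = DEFAULT_TWO_STATE_EQUILIBRIUM

    def inactive_probability(self, temperature: float) -> float:
        if self.inactive_fraction is not None:
            return self.inactive_fraction
        k = keq(self.equilibrium, temperature)
        return k / (1.0 + k)


@dataclass
class TwoStateTrajectory:
    """Output of :func:`gen_two_state_trajectory`."""

    temperature: float
    distances: np.ndarray
    intra_energies: np.ndarray
    solvent_energies: np.ndarray
    states: np.ndarray  # 0 = compact, 1 = extended
    ensemble: CoordinateEnsemble | None = None

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(f"# temperature_K: {float(self.temperature)!r}\n")
            handle.write(
                "distance_A,intra_energy_kcal_per_mol,solvent_energy_kcal_per_mol,state\n"
            )
            for d, ei, es, s in zip(
                self.distances, self.intra_energies, self.solvent_energies, self.states
            ):
                handle.write(f"{float(d)!r},{float(ei)!r},{float(es)!r},{int(s)}\n")

    @classmethod
    def read(cls, path) -> "TwoStateTrajectory":
        import pandas as pd

        temperature = 298.15
        with open(path, encoding="utf-8") as handle:
            first = handle.readline()
            if first.startswith("#") and "temperature_K" in first:
                temperature = float(first.split(":")[1])
        frame = pd.read_csv(path, comment="#")
        return cls(
            temperature=temperature,
            distances=frame["distance_A"].to_numpy(),
            intra_energies=frame["intra_energy_kcal_per_mol"].to_numpy(),
            solvent_energies=frame["solvent_energy_kcal_per_mol"].to_numpy(),
            states=frame["state"].to_numpy(),
        )


def gen_two_state_trajectory(
    spec: TwoStateSpec,
    temperature: float = 298.15,
    seed: int = 0,
    with_ensemble: bool = False,
) -> TwoStateTrajectory:
    """Draw a two-state end-to-end distance trajectory with linked energies.

    With ``with_ensemble=True`` a minimal two-atom coordinate ensemble
    realising the distances along the x axis is attached.
    """
    rng = np.random.default_rng(seed)
    p_inactive = spec.inactive_probability(temperature)
    states = (rng.random(spec.frames) < p_inactive).astype(int)
    means = np.where(states == 1, spec.extended_mean, spec.compact_mean)
    sds = np.where(states == 1, spec.extended_sd, spec.compact_sd)
    distances = np.abs(rng.normal(means, sds))
    intra = (
        spec.intra_intercept
        + spec.intra_slope * distances
        + rng.normal(0.0, spec.energy_noise_sd, spec.frames)
    )
    solvent = (
        spec.solvent_intercept
        + spec.solvent_slope * distances
        + rng.normal(0.0, spec.energy_noise_sd, spec.frames)
    )
    ensemble = None
    if with_ensemble:
        coords = np.zeros((spec.frames, 2, 3))
        coords[:, 1, 0] = distances
        ensemble = CoordinateEnsemble(
            coords=coords,
            atom_names=np.array(["C1", "C2"]),
            res_ids=np.array([1, 1]),
            res_names=np.array(["LIG", "LIG"]),
            chains=np.array(["A", "A"]),
        )
    return TwoStateTrajectory(float(temperature), distances, intra, solvent, states, ensemble)


# ---------------------------------------------------------------------------
# Coordinate ensembles


def gen_base_structure(n_residues: int = 30, chain: str = "A") -> CoordinateEnsemble:
    """A synthetic backbone (N, CA, C, O per residue) along an alpha-helical
    curve; a deterministic stand-in for a crystallographic model in tests
    and demos."""
    rise, turn_deg, radius = 1.5, 100.0, 2.3
    names, res_ids, coords = [], [], []
    offsets = {"N": (-0.5, -0.6, 0.0), "CA": (0.0, 0.0, 0.0),
               "C": (0.6, 0.5, 0.2), "O": (1.1, 1.3, 0.1)}
    for i in range(n_residues):
        angle = np.deg2rad(turn_deg * i)
        ca = np.array([radius * np.cos(angle), radius * np.sin(angle), rise * i])
        for name in ("N", "CA", "C", "O"):
            names.append(name)
            res_ids.append(i + 1)
            coords.append(ca + np.asarray(offsets[name]))
    n_atoms = len(names)
    return CoordinateEnsemble(
        coords=np.asarray(coords)[None, :, :],
        atom_names=np.array(names),
        res_ids=np.array(res_ids),
        res_names=np.full(n_atoms, "ALA"),
        chains=np.full(n_atoms, chain),
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    quat = rng.normal(size=4)
    return Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()


def gen_ensemble(
    base: CoordinateEnsemble,
    per_residue_sd,
    frames: int = 300,
    seed: int = 0,
    rigid_motions: bool = False,
    translation_scale: float = 5.0,
) -> CoordinateEnsemble:
    """Base structure plus per-atom isotropic Gaussian displacements.

    ``per_residue_sd`` is a scalar, a mapping res_id -> sd, or an array over
    the unique residue ids (A); each atom inherits its residue's sd.  With
    ``rigid_motions=True`` every frame additionally receives a uniformly
    random rotation about its centroid and a Gaussian translation, which
    superposition should remove.
    """
    if base.n_frames != 1:
        raise ValueError("base must be a single-frame ensemble")
    unique_res = np.unique(base.res_ids)
    if np.isscalar(per_residue_sd):
        sd_by_res = {int(r): float(per_residue_sd) for r in unique_res}
    elif isinstance(per_residue_sd, dict):
        sd_by_res = {int(k): float(v) for k, v in per_residue_sd.items()}
    else:
        arr = np.asarray(per_residue_sd, dtype=float)
        if arr.size != unique_res.size:
            raise ValueError("per_residue_sd must match the number of residues")
        sd_by_res = {int(r): float(s) for r, s in zip(unique_res, arr)}
    atom_sd = np.array([sd_by_res[int(r)] for r in base.res_ids])
    if np.any(atom_sd <= 0):
        raise ValueError("per-residue sds must be positive")

    rng = np.random.default_rng(seed)
    base_xyz = base.coords[0]
    noise = rng.normal(size=(frames, base.n_atoms, 3)) * atom_sd[None, :, None]
    coords = base_xyz[None, :, :] + noise
    if rigid_motions:
        for f in range(frames):
            rot = _random_rotation(rng)
            shift = rng.normal(0.0, translation_scale, 3)
            centroid = coords[f].mean(axis=0)
            coords[f] = (coords[f] - centroid) @ rot + centroid + shift
    return CoordinateEnsemble(
        coords=coords,
        atom_names=base.atom_names,
        res_ids=base.res_ids,
        res_names=base.res_names,
        chains=base.chains,
        b_factors=base.b_factors,
    )
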