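"""End-to-end orchestration: simulate -> cp-fit -> eq-fit -> conf-analyze.

A single structured config (YAML mapping, or an equivalent dict) drives all
stages; the CLI exposes the same stages individually.  Reports are written
twice: ``results.json`` (machine-readable, deterministic, numbers only — no
paths or timestamps, so identical config + seed reproduces it byte for
byte) and ``report.txt`` (human-readable).  Logging goes to stderr and never
feeds back into any numeric output.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import yaml

from .conformations import (
    CoordinateEnsemble,
    binned_energy_profile,
    distance_distribution,
    rmsf_per_residue,
    state_fractions,
    superpose_ensemble,
)
from .cp import HeatCapacityModel
from .energy import read_energy_table
from .equilibrium import EquilibriumParams, ITCSeries, fit_equilibrium
from .errors import PipelineError
from .synthetic import (
    ScanSpec,
    TwoStateSpec,
    gen_base_structure,
    gen_energy_scan,
    gen_ensemble,
    gen_itc_series,
    gen_two_state_trajectory,
)

__all__ = ["STAGES", "demo_config", "load_config", "run_pipeline", "RunReport"]

logger = logging.getLogger("thermocap.pipeline")

STAGES = ("simulate", "cp_fit", "eq_fit", "conf_analyze")


def _canon_stage(name: str) -> str:
    return name.replace("-", "_").strip().lower()


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as handle:
        config = yaml.safe_load(handle)
    if not isinstance(config, dict):
        raise PipelineError(f"{path}: config must be a mapping")
    return config


def demo_config() -> dict:
    """A small self-contained demo: all four stages from synthetic inputs."""
    return {
        "stages": ["simulate", "cp_fit", "eq_fit", "conf_analyze"],
        "simulate": {
            "scan": {"frames": 400, "replicas": 3},
            "itc": {
                "params": {"dh_eq": 17.86, "ds_eq": 0.0601, "dh_b": 3.69},
                "noise_sd": 0.1,
            },
            "two_state": {"frames": 4000, "temperature": 298.15},
            "ensemble": {"n_residues": 20, "frames": 120, "per_residue_sd": 0.3,
                         "rigid_motions": True},
        },
        "cp_fit": {"equilibration_fraction": 0.0, "block_count": 10},
        "eq_fit": {"dg_app_ref": [298.15, -12.54]},
        "conf_analyze": {
            "compact_cut": 8.0,
            "extended_cut": 11.0,
            "bin_width": 0.5,
            "range": [3.0, 20.0],
        },
    }


class RunReport:
    """Per-stage status and numeric results of one pipeline run."""

    def __init__(self, seed: int, config: dict):
        self.seed = seed
        self.config = config
        self.stages: dict[str, str] = {}
        self.results: dict[str, dict] = {}

    @property
    def ok(self) -> bool:
        return all(status == "ok" for status in self.stages.values())

    def to_dict(self) -> dict:
        return {"seed": self.seed, "stages": dict(self.stages), "results": self.results}

    def json(self) -> str:
        return json.dumps(_jsonify(self.to_dict()), indent=2, sort_keys=True)

    def text(self) -> str:
        lines = [f"thermocap pipeline run (seed {self.seed})", ""]
        for stage, status in self.stages.items():
            lines.append(f"[{status}] {stage}")
            for key, value in sorted(self.results.get(stage, {}).items()):
                lines.append(f"    {key} = {value}")
        return "\n".join(lines)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        value = float(obj)
        if math.isnan(value):
            return None
        return float(f"{value:.12g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _preflight(config: dict, stages: list[str]) -> None:
    """Fail before any output is written if referenced inputs are missing."""
    will_simulate = "simulate" in stages
    missing = []
    if "cp_fit" in stages and not will_simulate:
        for path in config.get("cp_fit", {}).get("energy_tables", []) or []:
            if not Path(path).exists():
                missing.append(str(path))
        if not config.get("cp_fit", {}).get("energy_tables"):
            missing.append("cp_fit.energy_tables (no simulate stage to provide them)")
    if "eq_fit" in stages and not will_simulate:
        path = config.get("eq_fit", {}).get("itc_path")
        if path is None:
            missing.append("eq_fit.itc_path (no simulate stage to provide it)")
        elif not Path(path).exists():
            missing.append(str(path))
    if "conf_analyze" in stages and not will_simulate:
        path = config.get("conf_analyze", {}).get("trajectory_path")
        if path is None:
            missing.append("conf_analyze.trajectory_path (no simulate stage to provide it)")
        elif not Path(path).exists():
            missing.append(str(path))
    if missing:
        raise PipelineError(f"missing pipeline inputs: {missing}")


def _stage_simulate(config: dict, seed: int, out_dir: Path, ctx: dict) -> dict:
    sim = config.get("simulate", {})
    results: dict = {}
    if "scan" in sim:
        scan_cfg = dict(sim["scan"])
        if "temperatures" in scan_cfg:
            scan_cfg["temperatures"] = tuple(scan_cfg["temperatures"])
        spec = ScanSpec(**scan_cfg)
        scan_set = gen_energy_scan(spec, seed=seed)
        paths = scan_set.write(out_dir / "energy")
        ctx["energy_tables"] = list(paths.values())
        results["true_delta_cp"] = spec.true_delta_cp
    if "itc" in sim:
        itc_cfg = dict(sim["itc"])
        params = EquilibriumParams(**itc_cfg.pop("params"))
        temps = itc_cfg.pop("temperatures", None)
        series = gen_itc_series(
            params, temps, noise_sd=itc_cfg.pop("noise_sd", 0.1), seed=seed + 1
        )
        path = out_dir / "itc.csv"
        series.write(path)
        ctx["itc_path"] = path
        results["itc_n_points"] = len(series)
    if "two_state" in sim:
        ts_cfg = dict(sim["two_state"])
        temperature = ts_cfg.pop("temperature", 298.15)
        eq_cfg = ts_cfg.pop("equilibrium", None)
        spec = TwoStateSpec(
            equilibrium=EquilibriumParams(**eq_cfg) if eq_cfg else None, **ts_cfg
        )
        traj = gen_two_state_trajectory(spec, temperature=temperature, seed=seed + 2)
        path = out_dir / "trajectory.csv"
        traj.write(path)
        ctx["trajectory_path"] = path
        results["two_state_inactive_probability"] = spec.inactive_probability(temperature)
    if "ensemble" in sim:
        ens_cfg = dict(sim["ensemble"])
        base = gen_base_structure(n_residues=ens_cfg.pop("n_residues", 20))
        ensemble = gen_ensemble(base, seed=seed + 3, **ens_cfg)
        path = out_dir / "ensemble.pdb"
        ensemble.to_pdb(path)
        ctx["ensemble_path"] = path
        results["ensemble_frames"] = ensemble.n_frames
    return results


def _stage_cp_fit(config: dict, out_dir: Path, ctx: dict) -> dict:
    cfg = dict(config.get("cp_fit", {}))
    paths = cfg.pop("energy_tables", None) or ctx.get("energy_tables")
    if not paths:
        raise PipelineError("cp_fit: no energy tables available")
    traces = []
    for path in paths:
        traces.extend(read_energy_table(path))
    model = HeatCapacityModel.from_traces(
        traces,
        equilibration_fraction=cfg.get("equilibration_fraction", 0.0),
        block_count=cfg.get("block_count", 10),
        n_water_imbalance=cfg.get("n_water_imbalance", 0),
        per_water_cp=cfg.get("per_water_cp", 0.018),
        expt_delta_cp=cfg.get("expt_delta_cp"),
    )
    res = model.fit()
    res.to_frame().to_csv(out_dir / "cp_table.csv")
    (out_dir / "cp_summary.txt").write_text(res.summary() + "\n", encoding="utf-8")
    out = {
        "delta_cp_kcal_per_mol_K": res.delta_cp,
        "delta_cp_se_kcal_per_mol_K": res.delta_cp_se,
    }
    for key, fit in res.fits.items():
        out[f"dudt_{key}"] = fit.slope
        out[f"r_squared_{key}"] = fit.r_squared
    return out


def _stage_eq_fit(config: dict, out_dir: Path, ctx: dict) -> dict:
    cfg = dict(config.get("eq_fit", {}))
    path = cfg.pop("itc_path", None) or ctx.get("itc_path")
    if path is None:
        raise PipelineError("eq_fit: no ITC series available")
    series = ITCSeries.read(path)
    dg_ref = cfg.get("dg_app_ref")
    res = fit_equilibrium(
        series,
        dg_app_ref=tuple(dg_ref) if dg_ref else None,
        branch=cfg.get("branch", "positive"),
    )
    res.to_frame().to_csv(out_dir / "eq_table.csv", index=False)
    (out_dir / "eq_summary.txt").write_text(res.summary() + "\n", encoding="utf-8")
    out = dict(res.derived_row())
    out.update({f"se_{k}": v for k, v in res.bse.items()})
    out["rss"] = res.rss
    return out


def _stage_conf_analyze(config: dict, out_dir: Path, ctx: dict) -> dict:
    from .synthetic import TwoStateTrajectory

    cfg = dict(config.get("conf_analyze", {}))
    traj_path = cfg.pop("trajectory_path", None) or ctx.get("trajectory_path")
    if traj_path is None:
        raise PipelineError("conf_analyze: no trajectory available")
    traj = TwoStateTrajectory.read(traj_path)
    bin_width = cfg.get("bin_width", 0.5)
    hist_range = tuple(cfg.get("range", (3.0, 20.0)))
    dist = distance_distribution(traj.distances, bin_width=bin_width, range=hist_range)
    fractions = state_fractions(
        traj.distances,
        compact_cut=cfg.get("compact_cut", 8.0),
        extended_cut=cfg.get("extended_cut", 11.0),
    )
    out = {
        "f_compact": fractions[0],
        "f_intermediate": fractions[1],
        "f_extended": fractions[2],
        "distance_modes_A": list(dist.modes(min_prob=0.01, min_separation=2.0)),
    }
    rows = ["bin_center_A,probability"]
    rows += [
        f"{float(c)!r},{float(p)!r}"
        for c, p in zip(dist.bin_centers, dist.probabilities)
    ]
    (out_dir / "distance_distribution.csv").write_text("\n".join(rows) + "\n")
    for tag, energies in (("intra", traj.intra_energies), ("solvent", traj.solvent_energies)):
        profile = binned_energy_profile(
            traj.distances, energies, bin_width=bin_width, range=hist_range
        )
        occ = profile.occupied
        slope = float(
            np.polyfit(profile.bin_centers[occ], profile.mean_energy[occ], 1)[0]
        )
        out[f"{tag}_energy_slope_kcal_per_mol_A"] = slope
        rows = ["bin_center_A,mean_energy_kcal_per_mol,count"]
        rows += [
            f"{float(c)!r},{float(m)!r},{int(n)}"
            for c, m, n in zip(profile.bin_centers, profile.mean_energy, profile.counts)
        ]
        (out_dir / f"energy_profile_{tag}.csv").write_text("\n".join(rows) + "\n")

    ens_path = cfg.pop("ensemble_path", None) or ctx.get("ensemble_path")
    if ens_path is not None:
        ensemble = CoordinateEnsemble.from_pdb(ens_path)
        aligned, _ = superpose_ensemble(ensemble, selection="CA")
        rmsf = rmsf_per_residue(aligned, selection="backbone")
        rmsf.to_csv(out_dir / "rmsf_per_residue.csv")
        out["rmsf_mean_A"] = float(rmsf.mean())
        out["rmsf_max_A"] = float(rmsf.max())
    return out


def run_pipeline(config: dict, seed: int | None = None, out_dir=None) -> RunReport:
    """Execute the configured stages in dependency order.

    ``seed`` and ``out_dir`` arguments override the config keys.  Every
    numeric result in the report carries its unit in the key name.  On a
    stage failure the report marks the stage ``failed``, downstream
    dependents are ``skipped``, and ``report.ok`` is False (the CLI turns
    that into a nonzero exit status).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    seed = int(seed if seed is not None else config.get("seed", 0))
    out_dir = Path(out_dir if out_dir is not None else config.get("out_dir", "thermocap_out"))
    stages = [_canon_stage(s) for s in config.get("stages", STAGES)]
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stage(s): {unknown}")
    stages = [s for s in STAGES if s in stages]  # dependency order

    _preflight(config, stages)
    out_dir.mkdir(parents=True, exist_ok=True)

    report = RunReport(seed, config)
    ctx: dict = {}
    failed = False
    runners = {
        "simulate": lambda: _stage_simulate(config, seed, out_dir, ctx),
        "cp_fit": lambda: _stage_cp_fit(config, out_dir, ctx),
        "eq_fit": lambda: _stage_eq_fit(config, out_dir, ctx),
        "conf_analyze": lambda: _stage_conf_analyze(config, out_dir, ctx),
    }
    for stage in stages:
        if failed:
            report.stages[stage] = "skipped"
            continue
        logger.info("running stage %s", stage)
        try:
            report.results[stage] = runners[stage]()
            report.stages[stage] = "ok"
        except Exception as exc:  # noqa: BLE001 - reported, not swallowed
            logger.error("stage %s failed: %s", stage, exc)
            report.stages[stage] = "failed"
            report.results[stage] = {"error": str(exc)}
            failed = True

    (out_dir / "results.json").write_text(report.json() + "\n", encoding="utf-8")
    (out_dir / "report.txt").write_text(report.text() + "\n", encoding="utf-8")
    return report
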