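"""Reading, validation and block-average summarisation of MD energy series.

The binding heat-capacity estimator consumes mean total potential energies
``<U>`` at a handful of temperatures for four system classes (holoprotein,
apoprotein, ligand in water, pure water).  This module turns raw per-frame
energy series into those per-temperature means, with uncertainties from block
averaging so that the strong frame-to-frame autocorrelation of MD energies
does not produce overconfident error bars.

File dialect
------------
Energy tables are plain delimited text.  Metadata lines start with ``#`` and
carry ``key: value`` pairs (``system``, ``temperature_K``, ``replica``, and
optionally ``frame_interval_ps``); each metadata block is followed by data
rows of ``time  energy`` pairs.  The delimiter of data rows is auto-detected
(comma if present, otherwise any whitespace).  A metadata line appearing
after data rows closes the current trace and opens a new block; keys not
repeated are inherited from the previous block.  Engine-specific binary
energy formats are deliberately not parsed.

Units: temperatures kelvin, energies kcal/mol, times picoseconds.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    EnergyTableParseError,
    InsufficientDataError,
    LabelMismatchError,
    SchemaError,
)

__all__ = [
    "EnergyTrace",
    "ScanPoint",
    "TemperatureScan",
    "trace_mean",
    "aggregate_scan",
    "read_energy_table",
    "write_energy_table",
    "read_scan",
    "write_scan",
]


@dataclass
class EnergyTrace:
    """One contiguous energy time series: a single system at one temperature.

    Parameters
    ----------
    system_label : str
        Which leg of the thermodynamic cycle the trace belongs to; by
        convention starts with one of ``holo``, ``apo``, ``lig``/``ligand``,
        ``wat``/``water``, optionally followed by a free-form tag.
    temperature : float
        Simulation temperature in kelvin (> 0).
    replica_id : int
        Index of the independent replica the frames come from.
    energies : numpy.ndarray
        Total potential energy per frame, kcal/mol; non-empty, all finite.
    frame_interval : float
        Time between stored frames in picoseconds (metadata only).
    """

    system_label: str
    temperature: float
    replica_id: int
    energies: np.ndarray
    frame_interval: float = 1.0

    def __post_init__(self):
        if not self.system_label:
            raise SchemaError("system_label must be a non-empty string")
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.ndim != 1 or self.energies.size == 0:
            raise ValueError("energies must be a non-empty 1-D series")
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("energies contain non-finite values")

    @property
    def n_frames(self) -> int:
        return int(self.energies.size)


@dataclass(frozen=True)
class ScanPoint:
    """One aggregated point of a temperature scan."""

    temperature: float
    mean_energy: float
    sem: float
    n_frames: int


@dataclass
class TemperatureScan:
    """Per-temperature mean energies for one system, ready for a dU/dT fit.

    Invariants: at least three points, strictly increasing temperatures,
    non-negative SEMs.
    """

    system_label: str
    points: list[ScanPoint] = field(default_factory=list)

    def __post_init__(self):
        if len(self.points) < 3:
            raise InsufficientDataError(
                f"a temperature scan needs >= 3 points, got {len(self.points)}"
            )
        temps = [p.temperature for p in self.points]
        if any(t2 <= t1 for t1, t2 in zip(temps, temps[1:])):
            raise ValueError("scan temperatures must be strictly increasing")
        if any(p.sem < 0 for p in self.points):
            raise ValueError("SEMs must be non-negative")

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([p.temperature for p in self.points])

    @property
    def mean_energies(self) -> np.ndarray:
        return np.array([p.mean_energy for p in self.points])

    @property
    def sems(self) -> np.ndarray:
        return np.array([p.sem for p in self.points])

    def __len__(self) -> int:
        return len(self.points)


def _trace_stats(
    trace: EnergyTrace, equilibration_fraction: float, block_count: int
) -> tuple[float, float, int]:
    """Mean, block SEM and retained frame count of one trace."""
    if not 0.0 <= equilibration_fraction < 1.0:
        raise ValueError("equilibration_fraction must be in [0, 1)")
    if block_count < 2:
        raise ValueError("block_count must be >= 2")
    energies = trace.energies
    start = int(math.floor(equilibration_fraction * energies.size))
    kept = energies[start:]
    if kept.size < block_count:
        raise InsufficientDataError(
            f"{kept.size} frames left after equilibration, need >= {block_count}"
        )
    mean = float(kept.mean())
    block_size = kept.size // block_count
    blocks = kept[: block_size * block_count].reshape(block_count, block_size)
    block_means = blocks.mean(axis=1)
    sem = float(block_means.std(ddof=1) / math.sqrt(block_count))
    return mean, sem, int(kept.size)


def trace_mean(
    trace: EnergyTrace,
    equilibration_fraction: float = 0.0,
    block_count: int = 10,
) -> tuple[float, float]:
    """Mean energy of a trace with a block-averaged standard error.

    The first ``floor(equilibration_fraction * n)`` frames are discarded; the
    mean is taken over all retained frames, and the SEM is the standard
    deviation (ddof=1) of ``block_count`` contiguous block means divided by
    ``sqrt(block_count)``.  Block averaging is the standard defence against
    the positive autocorrelation of MD energy series, for which the naive
    ``sd/sqrt(n)`` underestimates the true uncertainty.

    Returns
    -------
    (mean, sem) : tuple of float, kcal/mol
    """
    mean, sem, _ = _trace_stats(trace, equilibration_fraction, block_count)
    return mean, sem


def aggregate_scan(
    traces: list[EnergyTrace],
    equilibration_fraction: float = 0.0,
    block_count: int = 10,
) -> TemperatureScan:
    """Pool replicas of one system into a per-temperature scan.

    Replicas at the same temperature are pooled by frame-weighted mean; the
    pooled SEM treats replicas as independent:
    ``sem = sqrt(sum_i (n_i * sem_i)^2) / N``.
    """
    if not traces:
        raise InsufficientDataError("no traces given")
    labels = {t.system_label for t in traces}
    if len(labels) != 1:
        raise LabelMismatchError(f"mixed system labels in aggregation: {sorted(labels)}")
    (label,) = labels

    by_temp: dict[float, list[tuple[float, float, int]]] = {}
    for trace in traces:
        stats = _trace_stats(trace, equilibration_fraction, block_count)
        by_temp.setdefault(trace.temperature, []).append(stats)

    points = []
    for temp in sorted(by_temp):
        stats = by_temp[temp]
        n_total = sum(n for _, _, n in stats)
        mean = sum(n * m for m, _, n in stats) / n_total
        sem = math.sqrt(sum((n * s) ** 2 for _, s, n in stats)) / n_total
        points.append(ScanPoint(temp, mean, sem, n_total))
    return TemperatureScan(label, points)


# ---------------------------------------------------------------------------
# Delimited-text I/O

_META_RE = re.compile(r"^#\s*([A-Za-z_][A-Za-z0-9_]*)\s*[:=]\s*(.+?)\s*$")


def _split_row(line: str, delimiter: str | None) -> list[str]:
    if delimiter is not None:
        return [p for p in line.split(delimiter) if p != ""]
    if "," in line:
        return [p.strip() for p in line.split(",")]
    return line.split()


def read_energy_table(path, delimiter: str | None = None) -> list[EnergyTrace]:
    """Parse a delimited-text energy table into one trace per metadata block.

    Raises
    ------
    EnergyTableParseError
        On a malformed data row, naming the 1-based line number.
    SchemaError
        When a data block lacks the required metadata keys.
    """
    groups: dict[tuple[str, float, int], EnergyTrace] = {}
    order: list[tuple[str, float, int]] = []
    meta: dict[str, str] = {}
    energies: list[float] = []

    def flush():
        nonlocal energies
        if not energies:
            return
        if "system" not in meta:
            raise SchemaError(f"{path}: data block without a '# system:' header")
        if "temperature_K" not in meta:
            raise SchemaError(
                f"{path}: data block for system {meta['system']!r} lacks temperature_K"
            )
        trace = EnergyTrace(
            system_label=meta["system"],
            temperature=float(meta["temperature_K"]),
            replica_id=int(meta.get("replica", 0)),
            energies=np.array(energies),
            frame_interval=float(meta.get("frame_interval_ps", 1.0)),
        )
        key = (trace.system_label, trace.temperature, trace.replica_id)
        if key in groups:  # same group split over blocks: concatenate
            prev = groups[key]
            prev.energies = np.concatenate([prev.energies, trace.energies])
        else:
            groups[key] = trace
            order.append(key)
        energies = []

    with open(path, encoding="utf-8") as handle:
        for line_no, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                flush()
                match = _META_RE.match(line)
                if match:
                    meta[match.group(1)] = match.group(2)
                continue
            parts = _split_row(line, delimiter)
            if len(parts) < 2:
                raise EnergyTableParseError(line_no, f"expected (time, energy) pair, got {line!r}")
            try:
                float(parts[0])
                energy = float(parts[1])
            except ValueError:
                raise EnergyTableParseError(
                    line_no, f"non-numeric value in row {line!r}"
                ) from None
            energies.append(energy)
        flush()

    if not groups:
        raise SchemaError(f"{path}: no data rows found")
    return [groups[key] for key in order]


def write_energy_table(traces: list[EnergyTrace], path, delimiter: str = "\t") -> None:
    """Write traces in the dialect :func:`read_energy_table` understands.

    Energies are written with ``repr`` (shortest round-trip representation),
    so a write-then-read cycle reproduces the series exactly.
    """
    with open(path, "w", encoding="utf-8") as handle:
        for trace in traces:
            handle.write(f"# system: {trace.system_label}\n")
            handle.write(f"# temperature_K: {float(trace.temperature)!r}\n")
            handle.write(f"# replica: {trace.replica_id}\n")
            handle.write(f"# frame_interval_ps: {float(trace.frame_interval)!r}\n")
            for i, energy in enumerate(trace.energies.tolist()):
                time = i * float(trace.frame_interval)
                handle.write(f"{time!r}{delimiter}{energy!r}\n")


_SCAN_HEADER = "temperature_K,mean_energy_kcal_per_mol,sem_kcal_per_mol,n_frames"


def write_scan(scan: TemperatureScan, path) -> None:
    """Serialize a scan as CSV with a ``# system:`` header, full precision."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(f"# system: {scan.system_label}\n")
        handle.write(_SCAN_HEADER + "\n")
        for p in scan.points:
            handle.write(
                f"{float(p.temperature)!r},{float(p.mean_energy)!r},"
                f"{float(p.sem)!r},{int(p.n_frames)}\n"
            )


def read_scan(path) -> TemperatureScan:
    """Inverse of :func:`write_scan`."""
    label = None
    points = []
    with open(path, encoding="utf-8") as handle:
        for line_no, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            match = _META_RE.match(line)
            if match:
                if match.group(1) == "system":
                    label = match.group(2)
                continue
            if line.startswith("temperature_K"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 4:
                raise EnergyTableParseError(line_no, f"expected 4 columns, got {line!r}")
            try:
                points.append(
                    ScanPoint(float(parts[0]), float(parts[1]), float(parts[2]), int(parts[3]))
                )
            except ValueError:
                raise EnergyTableParseError(line_no, f"non-numeric value in {line!r}") from None
    if label is None:
        raise SchemaError(f"{path}: missing '# system:' header")
    return TemperatureScan(label, points)
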