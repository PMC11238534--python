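"""Trajectory and ensemble conformational analysis.

Covers the structural side of the heat-capacity story: end-to-end distance
distributions of a flexible ligand (compact, binding-competent conformers
near 5.5 A versus extended ones beyond ~11 A), distance-binned interaction
energy profiles, iterative least-squares ensemble superposition, average
structures, Ca RMSD, per-residue RMSF, and the isotropic B-factor
conversion ``RMSF = sqrt(3 B / (8 pi^2))``.

Coordinate ensembles are plain (frames, atoms, 3) arrays with per-atom
metadata; multi-model PDB files (MODEL/ENDMDL frames) are read and written
through biotite.  Residue numbering is preserved from the input, never
renumbered.

Atom selectors
--------------
Several operations take an atom selector, either an integer atom index or a
string of up to three ``/``-separated fields::

    "CA"          every atom named CA
    "12/CA"       atom CA of residue 12
    "A/12/CA"     atom CA of residue 12 in chain A

Operations that need a single atom (e.g. :func:`end_to_end_series`) raise
:class:`~thermocap.errors.SelectionError` unless the selector matches
exactly one atom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    AlignmentError,
    InsufficientDataError,
    SelectionError,
    UnalignedEnsembleWarning,
)

__all__ = [
    "CoordinateEnsemble",
    "DistanceDistribution",
    "EnergyProfile",
    "atom_indices",
    "resolve_atom",
    "end_to_end_series",
    "distance_distribution",
    "state_fractions",
    "binned_energy_profile",
    "superpose_ensemble",
    "ca_rmsd",
    "rmsf_per_atom",
    "rmsf_per_residue",
    "rmsf_from_bfactors",
    "bfactors_per_residue",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class CoordinateEnsemble:
    """An ordered stack of conformations sharing one atom table.

    ``coords`` has shape (n_frames, n_atoms, 3) in angstrom; the metadata
    arrays (``atom_names``, ``res_ids``, ``res_names``, ``chains``) have
    length n_atoms.  ``b_factors`` optionally carries the crystallographic
    temperature factors of the first model (A^2).
    """

    coords: np.ndarray
    atom_names: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    chains: np.ndarray
    b_factors: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates contain non-finite values")
        n = self.coords.shape[1]
        self.atom_names = np.asarray(self.atom_names, dtype=str)
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.res_names = np.asarray(self.res_names, dtype=str)
        self.chains = np.asarray(self.chains, dtype=str)
        for name in ("atom_names", "res_ids", "res_names", "chains"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have length {n}")
        if self.b_factors is not None:
            self.b_factors = np.asarray(self.b_factors, dtype=float)
            if self.b_factors.shape != (n,):
                raise ValueError(f"b_factors must have length {n}")

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.coords.shape[1])

    def with_coords(self, coords: np.ndarray) -> "CoordinateEnsemble":
        return CoordinateEnsemble(
            coords, self.atom_names, self.res_ids, self.res_names, self.chains,
            self.b_factors,
        )

    # -- multi-model PDB I/O (biotite) ---------------------------------

    @classmethod
    def from_pdb(cls, path) -> "CoordinateEnsemble":
        from biotite.structure.io.pdb import PDBFile

        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
        first = pdb.get_structure(model=1, extra_fields=["b_factor"])
        return cls(
            coords=stack.coord,
            atom_names=stack.atom_name,
            res_ids=stack.res_id,
            res_names=stack.res_name,
            chains=stack.chain_id,
            b_factors=np.asarray(first.b_factor, dtype=float),
        )

    def to_pdb(self, path) -> None:
        import biotite.structure as struc
        from biotite.structure.io.pdb import PDBFile

        stack = struc.AtomArrayStack(self.n_frames, self.n_atoms)
        stack.coord = self.coords
        stack.chain_id = self.chains
        stack.res_id = self.res_ids
        stack.res_name = self.res_names
        stack.atom_name = self.atom_names
        stack.hetero = np.zeros(self.n_atoms, dtype=bool)
        elements = [next((c for c in name if c.isalpha()), "C") for name in self.atom_names]
        stack.element = np.array(elements, dtype="U2")
        if self.b_factors is not None:
            stack.set_annotation("b_factor", self.b_factors)
        pdb = PDBFile()
        pdb.set_structure(stack)
        pdb.write(str(path))


@dataclass(frozen=True)
class DistanceDistribution:
    """Normalised end-to-end distance histogram.

    ``probabilities`` sum to 1 over the in-range bins; samples outside the
    histogram range are tallied in ``n_overflow``, never silently dropped.
    """

    bin_edges: np.ndarray
    probabilities: np.ndarray
    n_overflow: int = 0

    def __post_init__(self):
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, float))
        object.__setattr__(self, "probabilities", np.asarray(self.probabilities, float))
        if self.probabilities.size != self.bin_edges.size - 1:
            raise ValueError("need len(probabilities) == len(bin_edges) - 1")
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be non-negative")
        if not np.isclose(self.probabilities.sum(), 1.0):
            raise ValueError("probabilities must sum to 1")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def modes(self, min_prob: float = 0.0, min_separation: float = 0.0) -> np.ndarray:
        """Bin centers of the distribution's modes.

        A mode is a strict local maximum with probability > ``min_prob``;
        candidate maxima closer than ``min_separation`` (A) are merged,
        keeping the more probable one, so that counting noise riding on a
        broad peak is not reported as extra modes.
        """
        p = self.probabilities
        padded = np.concatenate([[-np.inf], p, [-np.inf]])
        is_max = (padded[1:-1] > padded[:-2]) & (padded[1:-1] > padded[2:])
        candidates = self.bin_centers[is_max & (p > min_prob)]
        if min_separation > 0 and candidates.size > 1:
            probs = p[is_max & (p > min_prob)]
            kept: list[float] = []
            for center in candidates[np.argsort(probs)[::-1]]:
                if all(abs(center - c) >= min_separation for c in kept):
                    kept.append(float(center))
            candidates = np.sort(kept)
        return candidates


@dataclass(frozen=True)
class EnergyProfile:
    """Mean energy per distance bin; empty bins are NaN with count 0."""

    bin_centers: np.ndarray
    mean_energy: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        for name in ("bin_centers", "mean_energy", "counts"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if not (self.bin_centers.size == self.mean_energy.size == self.counts.size):
            raise ValueError("profile arrays must have equal length")
        empty = self.counts == 0
        if not np.all(np.isnan(self.mean_energy[empty])):
            raise ValueError("empty bins must carry NaN, not a number")

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0


# ---------------------------------------------------------------------------
# Selection


def atom_indices(ensemble: CoordinateEnsemble, selection) -> np.ndarray:
    """Resolve a selection to an integer index array (see module docstring)."""
    if selection is None:
        return np.arange(ensemble.n_atoms)
    if isinstance(selection, (int, np.integer)):
        return np.array([int(selection)])
    if isinstance(selection, str):
        if selection == "backbone":
            return np.flatnonzero(np.isin(ensemble.atom_names, BACKBONE_ATOMS))
        fields = selection.split("/")
        mask = np.ones(ensemble.n_atoms, dtype=bool)
        if len(fields) == 1:
            (name,) = fields
        elif len(fields) == 2:
            res, name = fields
            mask &= ensemble.res_ids == int(res)
        elif len(fields) == 3:
            chain, res, name = fields
            mask &= (ensemble.chains == chain) & (ensemble.res_ids == int(res))
        else:
            raise SelectionError(f"bad selector {selection!r}")
        if name not in ("", "*"):
            mask &= ensemble.atom_names == name
        return np.flatnonzero(mask)
    arr = np.asarray(selection)
    if arr.dtype == bool:
        return np.flatnonzero(arr)
    return arr.astype(int)


def resolve_atom(ensemble: CoordinateEnsemble, selector) -> int:
    """A selector that must match exactly one atom."""
    idx = atom_indices(ensemble, selector)
    if idx.size != 1:
        raise SelectionError(f"selector {selector!r} matched {idx.size} atoms, need exactly 1")
    return int(idx[0])


# ---------------------------------------------------------------------------
# Distances and distributions


def end_to_end_series(ensemble: CoordinateEnsemble, atom_a, atom_b) -> np.ndarray:
    """Per-frame Euclidean distance (A) between two designated atoms."""
    i = resolve_atom(ensemble, atom_a)
    j = resolve_atom(ensemble, atom_b)
    delta = ensemble.coords[:, i, :] - ensemble.coords[:, j, :]
    return np.linalg.norm(delta, axis=1)


def distance_distribution(
    distances,
    bin_width: float = 0.5,
    range: tuple[float, float] = (3.0, 20.0),
) -> DistanceDistribution:
    """Normalised histogram of a distance series over a fixed range."""
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0:
        raise InsufficientDataError("empty distance series")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = range
    n_bins = int(np.ceil((hi - lo) / bin_width - 1e-9))
    edges = lo + bin_width * np.arange(n_bins + 1)
    inside = (distances >= lo) & (distances < edges[-1])
    n_overflow = int(distances.size - inside.sum())
    if not np.any(inside):
        raise InsufficientDataError("no distances inside the histogram range")
    counts, _ = np.histogram(distances[inside], bins=edges)
    return DistanceDistribution(edges, counts / counts.sum(), n_overflow)


def state_fractions(
    distances, compact_cut: float = 8.0, extended_cut: float = 11.0
) -> tuple[float, float, float]:
    """Fractions of frames that are compact, intermediate, and extended.

    Default cuts bracket the compact peak (~5.5 A) and the onset of the
    extended population (> 11 A).
    """
    if not compact_cut < extended_cut:
        raise ValueError("require compact_cut < extended_cut")
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0:
        raise InsufficientDataError("empty distance series")
    n = distances.size
    f_compact = float((distances <= compact_cut).sum() / n)
    f_extended = float((distances > extended_cut).sum() / n)
    return f_compact, 1.0 - f_compact - f_extended, f_extended


def binned_energy_profile(
    distances,
    energies,
    bin_width: float = 0.5,
    range: tuple[float, float] = (3.0, 20.0),
) -> EnergyProfile:
    """Mean per-frame energy as a function of the end-to-end distance."""
    distances = np.asarray(distances, dtype=float)
    energies = np.asarray(energies, dtype=float)
    if distances.shape != energies.shape:
        raise AlignmentError(
            f"distances ({distances.size}) and energies ({energies.size}) differ in length"
        )
    lo, hi = range
    n_bins = int(np.ceil((hi - lo) / bin_width - 1e-9))
    edges = lo + bin_width * np.arange(n_bins + 1)
    idx = np.digitize(distances, edges) - 1
    inside = (idx >= 0) & (idx < n_bins)
    counts = np.bincount(idx[inside], minlength=n_bins)
    sums = np.bincount(idx[inside], weights=energies[inside], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return EnergyProfile(centers, means, counts)


# ---------------------------------------------------------------------------
# Superposition, RMSD, RMSF


def _kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rotation matrix R with mobile @ R ~= target (both centred)."""
    h = mobile.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


def superpose_ensemble(
    ensemble: CoordinateEnsemble,
    selection=None,
    tol: float = 1e-6,
    max_iter: int = 100,
    return_history: bool = False,
):
    """Iteratively superpose all frames onto their running mean structure.

    Each iteration rigidly aligns every frame (least-squares Kabsch fit over
    the selection) to the current selection mean, then recomputes the mean;
    iteration stops once the mean shifts by less than ``tol`` A (RMS).  The
    total squared deviation of the selection to the running mean is
    non-increasing over iterations.

    Returns ``(aligned_ensemble, average_structure)``, the average over all
    atoms; with ``return_history=True`` also the list of per-iteration total
    squared deviations.
    """
    idx = atom_indices(ensemble, selection)
    if idx.size < 3:
        raise SelectionError(f"superposition needs >= 3 selected atoms, got {idx.size}")
    coords = ensemble.coords.copy()
    mean_sel = coords[0, idx].copy()
    history = []
    for _ in range(max_iter):
        mean_center = mean_sel.mean(axis=0)
        mean_centred = mean_sel - mean_center
        for f in range(coords.shape[0]):
            sel = coords[f, idx]
            center = sel.mean(axis=0)
            rot = _kabsch_rotation(sel - center, mean_centred)
            coords[f] = (coords[f] - center) @ rot + mean_center
        new_mean = coords[:, idx].mean(axis=0)
        history.append(float(((coords[:, idx] - new_mean) ** 2).sum()))
        shift = np.sqrt(((new_mean - mean_sel) ** 2).sum(axis=1).mean())
        mean_sel = new_mean
        if shift < tol:
            break
    aligned = ensemble.with_coords(coords)
    average = coords.mean(axis=0)
    if return_history:
        return aligned, average, history
    return aligned, average


def _single_frame_coords(structure, selection) -> np.ndarray:
    if isinstance(structure, CoordinateEnsemble):
        idx = atom_indices(structure, selection)
        if structure.n_frames != 1:
            raise AlignmentError("expected a single-frame structure")
        return structure.coords[0, idx]
    coords = np.asarray(structure, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("structure must be (n_atoms, 3) or a 1-frame ensemble")
    if selection is None:
        return coords
    return coords[np.asarray(selection, dtype=int)]


def ca_rmsd(structure_a, structure_b, selection=None) -> float:
    """RMSD (A) between two structures after optimal rigid superposition.

    Structures are (n, 3) arrays or single-frame ensembles; ``selection``
    picks the compared atoms (e.g. ``"CA"`` for the classic Ca RMSD).
    """
    a = _single_frame_coords(structure_a, selection)
    b = _single_frame_coords(structure_b, selection)
    if a.shape != b.shape:
        raise AlignmentError(f"atom count mismatch: {a.shape[0]} vs {b.shape[0]}")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    rot = _kabsch_rotation(a, b)
    diff = a @ rot - b
    return float(np.sqrt((diff**2).sum() / a.shape[0]))


def _check_alignment(coords_sel: np.ndarray) -> None:
    centroids = coords_sel.mean(axis=1)
    drift = np.linalg.norm(centroids - centroids.mean(axis=0), axis=1)
    if np.any(drift > 1.0):
        warnings.warn(
            "selection centroid drifts by > 1 A across frames; the ensemble "
            "does not look superposed - RMSF values will absorb rigid-body motion",
            UnalignedEnsembleWarning,
            stacklevel=3,
        )


def rmsf_per_atom(ensemble: CoordinateEnsemble, selection=None):
    """Root-mean-square fluctuation about the mean position, per atom (A)."""
    idx = atom_indices(ensemble, selection)
    coords = ensemble.coords[:, idx]
    _check_alignment(coords)
    mean = coords.mean(axis=0)
    rmsf = np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))
    return idx, rmsf


def rmsf_per_residue(ensemble: CoordinateEnsemble, selection="backbone"):
    """Per-residue RMSF: mean over each residue's selected atoms.

    ``selection="backbone"`` uses N/CA/C/O; any selector or index array
    works (e.g. ``"CA"`` for Ca-only fluctuations).  Returns a pandas
    Series indexed by residue id, preserving the input numbering.
    """
    import pandas as pd

    if isinstance(selection, str) and selection == "backbone":
        idx = np.flatnonzero(np.isin(ensemble.atom_names, BACKBONE_ATOMS))
    else:
        idx = atom_indices(ensemble, selection)
    if idx.size == 0:
        raise SelectionError("selection matched no atoms")
    _, rmsf = rmsf_per_atom(ensemble, idx)
    series = pd.Series(rmsf, index=ensemble.res_ids[idx])
    out = series.groupby(level=0).mean()
    out.index.name = "res_id"
    out.name = "rmsf_A"
    return out


def rmsf_from_bfactors(b):
    """Isotropic-harmonic conversion ``RMSF = sqrt(3 B / (8 pi^2))`` (A).

    ``b`` is a per-residue array of crystallographic temperature factors in
    A^2; B = 8 pi^2/3 maps to exactly 1 A.
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("B-factors must be non-negative")
    out = np.sqrt(3.0 * b / (8.0 * np.pi**2))
    return float(out) if out.ndim == 0 else out


def bfactors_per_residue(ensemble: CoordinateEnsemble, selection="CA"):
    """Average first-model B-factor per residue (pandas Series)."""
    import pandas as pd

    if ensemble.b_factors is None:
        raise ValueError("ensemble carries no B-factors")
    idx = atom_indices(ensemble, selection)
    series = pd.Series(ensemble.b_factors[idx], index=ensemble.res_ids[idx])
    out = series.groupby(level=0).mean()
    out.index.name = "res_id"
    out.name = "b_factor_A2"
    return out
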