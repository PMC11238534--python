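# Methods

This note documents the models implemented in `thermocap`, the conventions
and numerical choices behind them, what the synthetic-data generators do and
do not emulate, and the known limitations.

## The four-system ΔCp estimator

The heat capacity of a simulated system at constant composition is the
temperature derivative of its mean energy, so a binding heat-capacity change
can be obtained without any free-energy calculation from the slopes
∂⟨U⟩/∂T of four systems forming a closed cycle:

    ΔCp = (∂U/∂T|holo − ∂U/∂T|apo) − (∂U/∂T|lig − ∂U/∂T|wat)

The cycle is only meaningful when the upper pair (holo, apo) and the lower
pair (ligand-in-water, pure water) each contain identical numbers of water
molecules, because every degree of freedom contributes to Cp. When the water
counts differ, the correction `−n_imbalance × Cp(water)` is applied with the
experimental bulk value 0.018 kcal/mol/K per molecule (configurable).
Kinetic energy cancels everywhere in the cycle; it enters only through the
explicit 3R equipartition term of `per_molecule_cp`, which converts a
pure-solvent potential-energy slope into a total per-molecule heat capacity
(R = 0.0019872 kcal/mol/K throughout).

Conventions and numerics:

- **Per-point statistics.** Replicas at one temperature are pooled by
  frame-weighted mean. Each trace's mean carries a block-averaged SEM
  (default 10 contiguous blocks, sd of block means / √blocks), the standard
  defence against the strong positive autocorrelation of MD energy series;
  pooled SEMs combine replica SEMs in quadrature with frame weights.
- **Slope fits.** Ordinary (unweighted) least squares of the per-temperature
  means on temperature, written in closed form; the slope uncertainty is the
  asymptotic OLS standard error, and R² is conventional (defined as 1 when
  the total sum of squares vanishes). Unweighted OLS is used because the
  per-point SEMs are diagnostics of sampling quality, not heteroscedasticity
  of a known form, and because mean-energy–temperature relations of
  well-equilibrated systems are extremely linear (R² = 1 to many decimals).
- **Error propagation.** The ΔCp standard error is the quadrature sum of the
  four slope SEs; replicas do not enter a second time.
- **Defaults.** Equilibration fraction 0 (production series are assumed
  equilibrated upstream); block count 10; temperatures are expected to span
  roughly 283–303 K in ~5 K steps, but any ≥3 distinct temperatures work.

The constant-ΔCp van't Hoff model
`ΔG(T) = ΔH₀ − TΔS₀ + ΔCp[(T − T₀) − T ln(T/T₀)]` is provided as the
conventional integrated description (satisfying ΔCp = −T·∂²ΔG/∂T²). It is
linear in its three parameters, so `fit_vant_hoff` is an exact linear
least-squares solve. With realistic free-energy noise over a 20–30 K window
the curvature term is very poorly determined — the Monte-Carlo test in the
suite shows a ΔCp standard error several times |ΔCp| — which is precisely
why the derivative estimator above, not a van't Hoff fit to computed ΔG(T),
is the method of choice.

## The mandatory-coupling equilibrium model

Scheme: (E+L)′ ⇌ E+L → EL, where only the binding-competent state E+L can
form the complex and the primed state is an inactive conformer (of the free
enzyme or, in the system this package was built around, an extended
conformation of the free ligand). With
K_eq(T) = exp(−(ΔH_eq − TΔS_eq)/RT), the observables are

    ΔH_app(T)  = ΔH_b − ΔH_eq·K_eq/(1+K_eq)
    ΔCp_app(T) = −(ΔH_eq²/RT²)·p_active·p_inactive     (exact dΔH_app/dT)
    ΔG_app(T)  = ΔH_b − TΔS_b + RT·ln(1+K_eq)

ΔCp_app dips most strongly (−ΔH_eq²/4RT²) at the transition temperature
ΔH_eq/ΔS_eq and is nearly flat over a typical 290–310 K experimental window,
which is why calorimetric series are well described by a "constant" negative
ΔCp even when none is intrinsic.

Fitting conventions:

- Three parameters (ΔH_eq, ΔS_eq, ΔH_b) are estimated from ΔH_app(T) by
  Levenberg–Marquardt nonlinear least squares, multistarted from
  ΔH_eq ∈ {5, 10, 20, 40} kcal/mol with ΔS_eq = ΔH_eq/300 and ΔH_b at the
  mean observed enthalpy, keeping the lowest-RSS solution. The multistart
  guards against the two mirror minima and the flat directions that appear
  when the transition temperature falls outside the data range.
- Points are weighted 1/sd² when uncertainties are supplied, otherwise
  unweighted. Parameter SEs are asymptotic (pseudo-inverse of JᵀJ scaled by
  the residual variance); a pseudo-inverse is used deliberately so that
  near-degenerate fits report very large rather than spurious SEs.
- The model is evaluated through logistic/`log1p`-stable forms so extreme
  parameter regimes cannot overflow.
- **Two solutions.** ΔH_app data determine the parameters only up to the
  mirror transform (ΔH_eq, ΔS_eq, ΔH_b, ΔS_b) → (−ΔH_eq, −ΔS_eq,
  ΔH_b−ΔH_eq, ΔS_b−ΔS_eq), under which every observable is identical.
  Fits report the ΔH_eq > 0 branch (inactive state uphill at low
  temperature), the physically supported choice for the ligand
  compact/extended equilibrium; `alternate()` exposes the mirror, with the
  covariance transformed consistently.
- ΔS_b is not identified by enthalpies alone. When a reference apparent
  binding free energy (T_ref, ΔG_app) is supplied it is solved exactly from
  the free-energy expression; otherwise it is NaN and flagged.
- All "298 K" quantities use T_ref = 298.15 K.

## Conformational analysis

- **End-to-end distances** require explicit atom selectors (the two atoms
  defining "end-to-end" are a per-ligand modelling choice); distributions
  are probability-normalised histograms (default 0.5 Å bins over 3–20 Å)
  with out-of-range samples tallied, never dropped silently. Mode detection
  merges candidate maxima closer than a configurable separation (2 Å in the
  analyses here) so counting noise on a broad basin is not reported as extra
  states. Default state cuts: compact ≤ 8 Å, extended > 11 Å, bracketing
  the ~5.5 Å compact peak and the onset of the extended population; note
  the 11 Å reporting cut intentionally excludes part of the extended
  basin's left tail, so classification-style comparisons against a known
  two-state composition should cut near the inter-state midpoint instead.
- **Energy profiles** are per-bin means with empty bins carried as NaN plus
  a zero count (never as 0 energy).
- **Superposition** iterates: rigid-body least-squares (Kabsch, SVD with a
  determinant guard against reflections) of every frame onto the current
  selection mean, then mean update, until the mean moves < 1e-6 Å RMS (max
  100 iterations). The total squared deviation to the running mean is
  non-increasing by construction, which the suite asserts. Superposition is
  unweighted over the selection.
- **RMSF** is the per-atom root-mean-square deviation from the ensemble
  mean after superposition, averaged per residue over the selected atoms
  (backbone N/CA/C/O by default; Cα-only via selection). An ensemble whose
  selection centroid drifts > 1 Å across frames triggers a warning, not an
  error. Crystallographic B-factors convert through the isotropic harmonic
  relation RMSF = √(3B/8π²); anisotropic B-factors are out of scope.
- Multi-model PDB files are read and written with biotite; MODEL/ENDMDL
  records delimit frames and residue numbering is preserved, never
  renumbered.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of a spec and a seed (bit-reproducible)
and reproduce the *statistical* structure of the real inputs:

- `gen_energy_scan`: U_t = intercept + slope·T + stationary AR(1) noise.
  Default slopes (66.962/67.307/23.083/22.871 kcal/mol/K) are a realistic
  thrombin-inhibitor regime implying ΔCp = −0.557 kcal/mol/K; intercepts are
  arbitrary realistic droplet energies (−95000/−94800/−33500/−33200
  kcal/mol) — only slopes matter to the estimator, which the constant-shift
  invariance test guarantees. Noise sd 1 kcal/mol per frame and AR(1)
  coefficient 0.9 (correlation time ≈ 10 frames) make block averaging
  genuinely necessary; the real autocorrelation time of droplet MD energies
  is not better known, so 0.9 was fixed once as "strongly correlated".
  Default grid 283–303 K in 5 K steps, 5 replicas, 1000 frames per trace.
- `gen_itc_series`: ΔH_app(T) from the equilibrium model plus iid Gaussian
  noise (default sd 0.1 kcal/mol, nine temperatures 283–313 K).
- `gen_two_state_trajectory`: per-frame state drawn with inactive
  probability K_eq/(1+K_eq) at the requested temperature (or a direct
  fraction), distances Gaussian per state (compact 5.5 ± 0.7 Å, extended
  12.5 ± 1.8 Å — Gaussian by fiat; real distributions are only known to be
  uni-/bimodal histograms), and stylised linear energy trends (intra slope
  −2.5, ligand–water slope +3.5 kcal/mol/Å, noise sd 3 kcal/mol) encoding
  the qualitative picture: intramolecular electrostatics relax, solvation
  weakens, as the molecule opens.
- `gen_ensemble`: base structure (a synthetic backbone helix generator is
  provided) plus isotropic per-residue Gaussian displacements, optionally
  wrapped in uniform random rotations and Gaussian translations to exercise
  superposition.

Passing tests on these generators therefore demonstrate the correctness of
the estimators and fits *given* linear mean energies, Gaussian/AR(1) noise,
two Gaussian conformational states and harmonic fluctuations. They do not
demonstrate force-field accuracy, sufficiency of MD sampling, anharmonic
dynamics, or ITC baseline artefacts — none of which the package models.

## Pipeline

A YAML config drives simulate → cp-fit → eq-fit → conf-analyze. Referenced
input files are validated before any output is written; a stage failure
marks downstream stages skipped and the run failed (nonzero CLI exit).
Reports are duplicated as deterministic machine JSON (`results.json`, no
paths or timestamps, so identical config + seed reproduces it byte for
byte) and human text; units are embedded in key/column names. Logging is
strictly separated from numeric output. The bundled demo configuration uses
reduced problem sizes (3 replicas × 400 frames per energy trace, 4000
trajectory frames, 120 ensemble frames of a 20-residue backbone) chosen to
make the full demo essentially instantaneous while keeping every estimator
in its well-behaved regime; the statistical test suite uses comparable
sizes with 100-seed calibration checks.

## Known limitations

- Replicas are pooled before the slope fit; per-replica slope fits averaged
  afterwards would give slightly different (usually indistinguishable)
  errors. Pooling matches the one-⟨U⟩-per-temperature reporting convention.
- Cp from energy-fluctuation variance (⟨δU²⟩/kT²) is deliberately not
  implemented; the derivative route is the method of record here.
- The equilibrium model covers mandatory coupling only — no binding from
  both conformers, no protonation-linked or aggregation equilibria, no raw
  thermogram fitting.
- Energy-table parsing covers the package's own delimited dialect;
  engine-specific binary formats need external conversion.
- B-factor conversion assumes isotropic harmonic disorder and ignores
  static/lattice contributions, so MD-vs-crystal RMSF comparisons are
  qualitative.
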