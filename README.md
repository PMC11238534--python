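# thermocap

Heat-capacity effects in protein–ligand binding: estimation of the binding
heat-capacity change ΔC<sub>p</sub> from molecular-dynamics energy scans, a
conformational-equilibrium model for calorimetric (ITC) binding enthalpies,
and conformational/fluctuation analysis of coordinate ensembles.

## Who this is for

Computational chemists and biophysicists who want to (i) turn per-frame MD
potential energies at several temperatures into an absolute binding
ΔC<sub>p</sub> with honest error bars, (ii) interpret temperature-dependent
ITC enthalpies with a two-state ("mandatory coupling") equilibrium model, and
(iii) connect both to ligand conformational behaviour (compact vs extended
conformers, RMSF, B-factors). A synthetic-data module generates every input
with the statistical structure of the real thing, so the full pipeline runs
and is tested without any MD engine or downloads.

## The science in brief

**Four-system ΔCp estimator.** The heat capacity of a simulated system is the
temperature derivative of its mean energy. For binding, compare four systems
that form a closed cycle with equal numbers of degrees of freedom —
holoprotein, apoprotein, ligand in water, pure water:

    ΔCp = (∂U/∂T|holo − ∂U/∂T|apo) − (∂U/∂T|lig − ∂U/∂T|wat)

Each slope comes from an ordinary least-squares fit of ⟨U⟩ versus T (the
relationship is essentially perfectly linear, R² ≈ 1); the ΔCp error is the
quadrature sum of the four asymptotic slope errors. A residual water-count
imbalance between holo and apo is corrected with the bulk-water value of
0.018 kcal/mol/K per molecule, and the 3R equipartition term converts
potential-energy slopes to total per-molecule heat capacities when needed.

**Mandatory-coupling equilibrium model.** A two-state equilibrium
(E+L)′ ⇌ E+L → EL, in which only one conformer binds, produces apparent
observables

    K_eq(T)   = exp(−(ΔH_eq − T·ΔS_eq)/RT)
    ΔH_app(T) = ΔH_b − ΔH_eq·K_eq/(1+K_eq)
    ΔCp_app(T)= −(ΔH_eq²/RT²)·[1/(1+K_eq)]·[K_eq/(1+K_eq)]
    ΔG_app(T) = ΔH_b − T·ΔS_b + RT·ln(1+K_eq)

so a modest conformational equilibrium of the *free* ligand (compact,
binding-competent conformers near 5.5 Å end-to-end distance versus extended
ones beyond 11 Å) yields an apparently constant negative ΔC<sub>p</sub> of a
few tenths of a kcal/mol/K over a typical experimental window — with no
intrinsic heat-capacity difference at all. The model always has two mirror
parameter solutions with identical observables; `alternate_solution` maps
between them.

## Worked example

```python
import thermocap as tc

# --- binding dCp from a (synthetic) four-system energy scan -------------
spec = tc.ScanSpec(frames=400, replicas=3)          # AR(1) noise, 283-303 K
scans = tc.gen_energy_scan(spec, seed=1).scans()
model = tc.HeatCapacityModel(scans["holo"], scans["apo"], scans["lig"], scans["wat"])
res = model.fit()
print(res.summary())

# --- equilibrium model fitted to a (synthetic) ITC series ---------------
truth = tc.EquilibriumParams(dh_eq=17.86, ds_eq=0.0601, dh_b=3.69)
series = tc.gen_itc_series(truth, noise_sd=0.1, seed=42)
eq = tc.fit_equilibrium(series, dg_app_ref=(298.15, -12.54))
print(f"dH_eq = {eq.params.dh_eq:.2f} +/- {eq.bse['dh_eq']:.2f} kcal/mol")
print(f"dCp_app(298 K) = {eq.predict_cp(298.15):.3f} kcal/mol/K")
```

This prints (abridged):

```
Binding heat capacity (four-system dU/dT estimator)

system      dU/dT        se        R^2   n
holo       66.966    0.0091   1.000000   5
apo        67.303    0.0046   1.000000   5
lig        23.084    0.0094   1.000000   5
wat        22.876    0.0055   1.000000   5

water imbalance correction: +0.0000 kcal/mol/K
delta_Cp = -0.546 +/- 0.015 kcal/mol/K
dH_eq = 17.90 +/- 0.09 kcal/mol
dCp_app(298 K) = -0.452 kcal/mol/K
```

The estimate −0.546 ± 0.015 kcal/mol/K sits within one standard error of the
generator's true value of −0.557 (the difference of the prescribed slopes);
the equilibrium fit recovers the prescribed ΔH<sub>eq</sub> = 17.86 kcal/mol
within half a standard error and predicts the familiar ≈ −0.4 kcal/mol/K
apparent heat capacity.

A command-line interface covers the same ground:

```bash
thermocap run --seed 7 --out demo_out          # simulate + all analyses
thermocap cp-fit demo_out/energy/*.tsv
thermocap eq-fit demo_out/itc.csv --dg-app-ref 298.15 -12.54
thermocap conf-analyze demo_out/trajectory.csv
```

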