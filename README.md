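# ticycle

Thermodynamic-integration (TI) free-energy estimation, thermodynamic-cycle
ΔΔG analysis with error propagation, and protein-interface interaction
metrics — with synthetic generators that make the whole pipeline testable
against exact ground truth.

## The problem

Alchemical free-energy calculations quantify how a chemical change to a
residue (for example an oxidative modification such as lysine
carbonylation or cysteine oxidation to cysteic acid) shifts the stability
of a protein complex. The change is coupled to a parameter λ ∈ [0, 1]
interpolating the force-field parameters between the native (A) and
modified (B) end states, and the free-energy change of one leg is

    ΔG = ∫₀¹ ⟨∂H/∂λ⟩_λ dλ .

Running the same alchemical transformation in the homodimer, the folded
monomer, and an unfolded-state model closes thermodynamic cycles that give
the physically interesting quantities

    ΔΔG_dimerization = ΔG_dim − 2·ΔG_mono     (homodimer: two identical monomers)
    ΔΔG_folding      = ΔG_mono − ΔG_unf

with positive values meaning the modification destabilizes the dimer
(monomer). `ticycle` implements everything downstream of the sampling
engine: parsing per-λ, per-replica ∂H/∂λ time series, discarding the
equilibration transient, pooling replicas with block-averaged standard
errors, integrating over the λ schedule with a generalized Simpson rule
for non-equidistant nodes, propagating errors to ΔG and through the cycle
to ΔΔG, classifying effects against their uncertainties, and reporting
convergence diagnostics against the 2RT ≈ 5 kJ/mol yardstick.

Because production molecular dynamics is far beyond desk scale, the
package ships two validation routes with *exact* ground truth:

* **AR(1) surrogates** (`ticycle.synthetic_data`): ∂H/∂λ series with a
  known smooth mean curve g(λ) and autocorrelated noise, so the estimator
  can be scored against ∫g dλ in closed form;
* **a toy alchemical system** (`ticycle.toy_alchemy`): a few tethered
  particles whose pair interactions switch off through the Beutler
  soft-core coupling, sampled by Metropolis Monte Carlo, with ΔG known
  exactly from dense quadrature of the configuration integrals.

A third module (`ticycle.struct_metrics`) implements the per-residue
interface metrics used to compare native and modified structures:
Kabsch-fit RMSD, per-residue RMSF, nonbonded interaction energy under
reaction-field electrostatics (r_c = 1.4 nm, ε_rf = 65), geometric
hydrogen-bond counts (0.35 nm / 30°), and counts of oppositely charged
groups within 0.3 / 0.6 nm.

## Worked example

`examples/02_thermodynamic_cycle.py` generates a complete synthetic study
(three legs × 25 λ-points × 9 replicas × 500 ps at 1 ps sampling),
estimates each leg, and closes the cycle:

```
dG_dimer     =  28.844 +/- 0.273 kJ/mol (truth 29.0)
dG_monomer   =  10.991 +/- 0.270 kJ/mol (truth 11.0)
dG_unfolded  =   4.174 +/- 0.276 kJ/mol (truth 4.0)
ddG_dimerization = 6.862 +/- 0.605 kJ/mol [destabilizing]  (truth 7.0)
ddG_folding      = 6.816 +/- 0.386 kJ/mol [destabilizing]  (truth 7.0)
mean per-lambda SEM = 1.15 kJ/mol; 2RT reference = 4.99 kJ/mol
```

Each leg's ΔG recovers the planted integral within its propagated error;
the cycle ΔΔGs recover the planted destabilization (7 kJ/mol) and are
labelled `destabilizing` because they exceed 1σ; per-λ errors sit well
below the 2RT convergence yardstick. The other examples demonstrate a
single-leg estimate (`01`), validation against the exact toy-physics
oracles (`03`), and the interface-metrics table on a structure with
planted interactions (`04`).

The same pipeline is scriptable from a shell:

```sh
ticycle synth --out study/                # generate a synthetic study
ticycle estimate --study study/           # per-leg TI estimates
ticycle cycle --study study/              # ddG table + convergence report
ticycle structmetrics --structure ref.pdb --trajectory traj.pdb --residues 1
```

All commands accept `--config config.yaml`; defaults mirror the reference
protocol (21 + 2×2 λ-nodes, 9 replicas × 500 ps, last 150 ps retained,
300 K).

## Layout

- `src/ticycle/ti_core.py` — series parsing, equilibration discard,
  blocking, replica pooling, λ schedules, generalized Simpson quadrature,
  ΔG estimation with error propagation
- `src/ticycle/thermo_cycle.py` — cycle ΔΔGs, classification, population
  ratios, convergence reporting
- `src/ticycle/toy_alchemy.py` — soft-core toy Hamiltonian, Metropolis
  sampler, exact partition-function oracles
- `src/ticycle/synthetic_data.py` — AR(1) surrogates, planted structures,
  jittered trajectories, file writers
- `src/ticycle/struct_metrics.py` — RMSD/RMSF, reaction-field energies,
  H-bonds, charge contacts
- `src/ticycle/cli.py` — the `ticycle` command
- `docs/methods.md` — models, assumptions, numerical choices
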