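# Methods

## The estimator

The free-energy change of one alchemical leg is the thermodynamic
integral ΔG = ∫₀¹ ⟨∂H/∂λ⟩_λ dλ, estimated from per-λ, per-replica time
series of the Hamiltonian derivative. The processing chain is:

1. **Equilibration discard.** Each series keeps only the samples with
   time > t_end − keep_last, with keep_last = 150 ps by default on a
   500 ps production window. The rule uses the series' own final time, so
   a truncated series degrades gracefully (with a warning) instead of
   failing; a series shorter than the window is returned whole.

2. **Block-averaged errors.** Within a replica, the standard error of the
   mean is estimated by Flyvbjerg–Petersen blocking: adjacent samples are
   repeatedly pair-averaged and the naive SEM √(var/n) is recorded at each
   level. The reported value is the first level whose estimate changed by
   less than 10% over two successive doublings (the plateau); when no
   plateau appears before fewer than 8 blocks remain, the deepest level's
   estimate is used. For uncorrelated data this reduces to s/√n; for
   positively autocorrelated data it converges to the
   effective-sample-size SEM s·√((1+φ)/(1−φ))/√n, which the tests verify
   on AR(1) noise with φ = 0.9.

3. **Replica pooling.** The per-λ mean pools all retained samples. Two
   SEM estimates are formed: the within-replica block SEMs combined as
   √(Σ sem_i²)/R, and the cross-replica scatter sd(replica means)/√R.
   The larger of the two is reported. The first is correct when replicas
   share a common stationary distribution; the second catches
   between-replica heterogeneity (distinct conformational substates) that
   within-replica blocking cannot see. A single replica degenerates to
   its block SEM.

4. **λ schedule.** Default: 21 uniform nodes on [0, 1] plus two extra
   nodes near each end, 25 nodes in total. The extra nodes sit at
   0.0125 and 0.0375 (mirrored near λ = 1), quartering the first and last
   uniform interval; their exact positions are configurable. End-point
   refinement resolves the curvature introduced by soft-core switching,
   which is strongest where interactions appear or vanish.

5. **Quadrature.** The generalized Simpson rule for non-equidistant
   nodes: consecutive interval pairs are integrated under the quadratic
   through their three nodes. When the interval count is odd, the final
   interval is integrated under the quadratic through the *last three*
   nodes rather than by the trapezoid rule; this keeps the rule exact for
   every quadratic on every node layout (a property the test suite checks
   on 1000 random layouts), which a trapezoid tail would break at first
   order. Only a two-node schedule falls back to the trapezoid. The rule
   is exposed both as an integral and as explicit weights w_i, verified
   to reproduce the integral on basis vectors to machine precision.

6. **Error propagation.** ΔG = Σ w_i·mean_i with
   σ² = Σ w_i²·sem_i², treating λ-points as statistically independent
   (each node is sampled by separate simulations). Cycle combinations
   follow the same independence assumption:
   ΔΔG_dim = ΔG_dim − 2·ΔG_mono with σ² = σ_dim² + 4σ_mono², and
   ΔΔG_fold = ΔG_mono − ΔG_unf with σ² = σ_mono² + σ_unf². The factor 2
   encodes homodimer symmetry — one monomer leg is doubled rather than
   accepting two monomer legs. A Monte-Carlo check (10⁴ Gaussian
   perturbations of the legs) confirms the variance formula to a few
   percent.

7. **Classification and diagnostics.** An effect is labelled
   `insignificant` when |ΔΔG| ≤ m·σ (default multiplier m = 1,
   configurable), otherwise `destabilizing`/`stabilizing` by sign
   (positive = the modification destabilizes the dimer or monomer). The
   convergence report gives the fraction of per-λ SEMs below each
   threshold (default 10 and 20 kJ/mol), the mean SEM, the 2RT reference
   (4.99 kJ/mol at 300 K, R = 0.008314 kJ/mol/K), and flags a system as
   unconverged when more than 20% of its SEMs exceed 20 kJ/mol — the
   exclusion rule for systems whose sampling has not converged. The
   population-ratio helper exp(ΔΔG/RT) converts a folding ΔΔG into the
   fold-change of the unfolded:folded ratio.

## The toy alchemical system

`toy_alchemy` is a desk-scale surrogate for the sampling engine: at most
four particles in 1–3 dimensions, each held by a harmonic tether
(0.5·k(λ)·|x−c|², k interpolated linearly between end states), with
pairwise LJ + Coulomb interactions coupled to λ through the Beutler
soft-core scheme in the GROMACS convention:

    V(r, λ) = (1−λ)·V_A(r_A) + λ·V_B(r_B)
    r_A = (α σ_A⁶ λ^p + r⁶)^{1/6},  r_B = (α σ_B⁶ (1−λ)^p + r⁶)^{1/6}

with σ⁶ = c12/c6 (set to 1 nm⁶ when either coefficient vanishes).
Defaults α = 0.7, p = 1; the alternative (α = 1.51, p = 2) used for
threonine-type transformations is supported as given. The coupling is
exactly the plain A-state (B-state) potential at λ = 0 (λ = 1) and finite
at r = 0 for interior λ when α > 0. ∂H/∂λ is analytic (tether term plus
the chain-rule derivative through r_A, r_B) and is verified against
central finite differences at 10⁻⁶ relative tolerance.

Sampling is single-particle-displacement Metropolis with uniform
proposals; the step size is tuned during a discarded warm-up (default
max(500, n_steps/5) steps) by proportional adjustment toward 50%
acceptance, clipped to [0.5×, 2×] per 100-step window. Chains are
bit-reproducible given a seed; a run that accepts no moves raises an
error.

Two oracles close the loop. `exact_delta_g` evaluates
−RT ln(Z₁/Z₀) by dense tensor-grid quadrature (trapezoid per axis,
default 401 points per degree of freedom over ±8 thermal widths
√(RT/k_min)), feasible up to 3 degrees of freedom; grid-doubling changes
the result by < 10⁻⁴ kJ/mol on the shipped fixtures. `exact_dhdl_mean`
computes the per-λ ensemble average the same way, isolating quadrature
bias from sampler bias (on the default 25-node schedule the Simpson
discretization bias of the pair system is ~0.003 kJ/mol, far below the
statistical σ ≈ 0.06).

**Ergodicity constraint (1D systems).** In one dimension a Metropolis
chain cannot cross an LJ core, so the two particle orderings are separate
ergodic components, while the quadrature oracle integrates over both. The
shipped pair fixture therefore uses stiff tethers
(k = 150 kJ/mol/nm²) that suppress the swapped-ordering basin to ~e⁻¹⁹
of Z; with soft tethers (k = 30) the neglected basin holds ~0.3% of Z
and produces a measurable one-sided bias (~+0.2 kJ/mol). Any
user-defined 1D system should respect the same constraint, or the oracle
and the sampler answer different questions.

## The AR(1) surrogate

`synthetic_data.gen_ar1_dhdl` emulates the statistical structure of
production ∂H/∂λ traces: a smooth polynomial mean curve g(λ) plus
stationary AR(1) noise x_{t+1} = φ·x_t + ε, ε ~ N(0, σ_n²). The first
deviation is drawn from the stationary distribution (variance
σ_n²/(1−φ²)), so closed-form variance and autocorrelation checks hold
from the first sample and no burn-in is needed. Replica r of a study
seeds its generator with (master + r, λ-key), keeping replicas and
λ-points mutually independent and every study reproducible. The true
integral ∫₀¹ g dλ is available term-wise, giving exact recovery targets.

Default study conditions mirror the reference protocol: 25 λ-nodes,
9 replicas, 500 samples at 1 ps spacing per replica (last 150 retained),
σ_n = 8 kJ/mol and φ = 0.8 — an autocorrelation time of a few ps and
per-λ SEMs of ~1 kJ/mol after pooling, comfortably below the 2RT
yardstick, as expected for converged sampling. What the surrogate does
*not* emulate: non-stationary drift, conformational substates (replica
heterogeneity), fat-tailed ∂H/∂λ distributions near soft-core endpoints,
or any force-field physics. Passing recovery tests therefore validates
the estimator's statistics, not the realism of any molecular model.

## Structural fixtures and metrics

Planted structures place a central charged residue (a lysine-like NZ
group at the origin) and partner groups on well-separated unit rays:
salt-bridge partners (glutamate-like carboxylates) in the upper
hemisphere at stated minimum-atom distances, hydrogen-bond complexes
(one donor N–H per bond, ideal linear D–H···A, plus optional bent decoys)
on a hub 0.9 nm below. Ray separation guarantees no unplanned pair can
satisfy the default criteria, so metric outputs must equal the manifest
exactly. Trajectories add isotropic Gaussian jitter of amplitude σ_a per
coordinate (population RMSF = σ_a√3), optionally composed with random
rigid motions that a Kabsch fit must remove.

Metric conventions:

* **Superposition** uses scipy's `Rotation.align_vectors` (Kabsch/SVD);
  the post-fit RMSD is recomputed directly from the transformed
  coordinates because the solver's reported residual suffers catastrophic
  cancellation for near-exact superpositions (~10⁻⁸ where the true value
  is ~10⁻¹⁶).
* **RMSF** is the per-atom fluctuation about the time-mean position,
  averaged over the residue's atoms, on pre-fitted frames.
* **Interaction energy** sums, over pairs (residue atom, environment
  atom) within r_c, the LJ term and the reaction-field Coulomb term
  f·q_iq_j·(1/r + k_rf·r² − c_rf) with
  k_rf = (ε_rf−1)/((2ε_rf+1)·r_c³), c_rf = 1/r_c + k_rf·r_c², which
  vanishes continuously at the cutoff by construction. Defaults
  r_c = 1.4 nm, ε_rf = 65, f = 138.935458 kJ·mol⁻¹·nm·e⁻². No periodic
  boundaries: fixtures are non-periodic by design.
* **Hydrogen bonds**: donor–acceptor distance ≤ 0.35 nm and H–D–A angle
  ≤ 30°, the standard geometric convention of MD analysis tools. By
  default every N*/O* atom with a covalently attached hydrogen (within
  0.115 nm, same residue) donates and every N*/O* atom accepts;
  explicit donor tables are validated (a listed donor without a hydrogen
  is an error). Only residue↔environment bonds are counted.
* **Charge contacts**: formal charges live on named side-chain groups in
  a small editable lookup (lysine amine, arginine guanidinium,
  aspartate/glutamate carboxylate, cysteic-acid sulfonate, doubly
  protonated histidine); group–group distance is the minimum over member
  atoms. Counts at 0.3 and 0.6 nm are cumulative (count(0.3) ≤
  count(0.6)); the 0.3–0.6 annulus count is reported alongside, covering
  both possible readings of a "0.3–0.6 nm range".

The minimal-PDB dialect stores the partial charge in the occupancy
column (PDB has no charge field), writes coordinates in Å per PDB
convention, and converts to nm on reading; multi-frame trajectories are
multi-MODEL files. The dialect is written and parsed only by this
package. Fixed-format coordinates quantize to 10⁻⁴ nm, so tests that
require 10⁻⁶ nm manifest accuracy operate on the in-memory structure.

## Problem sizes and determinism

The shipped validation workloads are sized for a laptop-class single
core: surrogate recovery uses 100 studies of 25 λ × 9 replicas × 500
samples (~30 s); the physics oracles use 3 replicas per λ with
12 000–20 000 Metropolis steps (~1 min together); blocking accuracy uses
10⁵-sample series. Every random quantity is driven by an explicit seed —
generators, samplers, and the acceptance script (which derives all its
sub-seeds from `--seed`) — so reruns are bit-reproducible.

## Known limitations

* The estimator treats λ-points as independent; correlated λ-ensembles
  (e.g., from replica exchange) would need a joint error model.
* Blocking needs ≥ 8 samples and underestimates errors when the
  autocorrelation time approaches the retained window; the cross-replica
  scatter term partially compensates.
* The plateau rule (10% over two doublings) can trigger slightly early on
  strongly correlated series, biasing SEMs a few percent low — within
  the tolerances validated here.
* The toy sampler is not an MD engine: no kinetic energy, no barostat,
  and single-particle moves only; it validates statistics, not dynamics.
* `exact_delta_g` is limited to ≤ 3 degrees of freedom by dense-grid
  cost.
* Interface metrics implement the stated nonbonded scheme only — no
  bonded terms, exclusions, or 1–4 scaling — and are meant for
  fixture-scale structures, not solvated boxes.
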