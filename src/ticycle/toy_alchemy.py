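"""Desk-scale lambda-coupled alchemical system with an exact free-energy oracle.

A handful of particles carry pairwise Lennard-Jones + Coulomb interactions
whose parameters interpolate between an A (native) and a B (modified) end
state through the Beutler soft-core coupling, plus harmonic tethers that
keep all configuration integrals finite.  The system is small enough that
Z(lambda) can be evaluated by dense quadrature, giving an exact dG against
which the thermodynamic-integration pipeline is validated; a Metropolis
sampler plays the role of the MD engine, emitting dH/dlambda time series.

Soft-core convention (the one implemented by GROMACS):

    V(r, lam) = (1-lam) V_A(r_A) + lam V_B(r_B)
    r_A = (alpha sigma_A^6 lam^p     + r^6)^(1/6)
    r_B = (alpha sigma_B^6 (1-lam)^p + r^6)^(1/6)

with sigma^6 = c12/c6 (1 nm^6 when either coefficient vanishes).  V_X is
the plain LJ + Coulomb pair energy of end state X.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ti_core import DhdlSeries
from .units import F_COULOMB, R_GAS

__all__ = [
    "NonbondedPairState",
    "SoftCoreParams",
    "Tether",
    "ToyAlchemicalSystem",
    "softcore_pair_energy",
    "dhdl_analytic",
    "mc_sample_dhdl",
    "exact_delta_g",
    "exact_dhdl_mean",
    "SamplingError",
]


class SamplingError(RuntimeError):
    """Raised when the Metropolis chain accepts no moves at all."""


@dataclass(frozen=True)
class NonbondedPairState:
    """End-state nonbonded parameters of one particle pair.

    c6, c12 are the LJ dispersion/repulsion coefficients in
    kJ mol^-1 nm^6 and kJ mol^-1 nm^12; q_i, q_j are partial charges (e).
    """

    c6: float = 0.0
    c12: float = 0.0
    q_i: float = 0.0
    q_j: float = 0.0

    def __post_init__(self):
        if self.c6 < 0 or self.c12 < 0:
            raise ValueError("LJ coefficients must be non-negative")

    @property
    def sigma6(self) -> float:
        """sigma^6 in nm^6 used by the soft-core radius; 1 when degenerate."""
        if self.c6 > 0 and self.c12 > 0:
            return self.c12 / self.c6
        return 1.0


@dataclass(frozen=True)
class SoftCoreParams:
    """Soft-core height alpha (dimensionless) and lambda power p >= 1."""

    alpha: float = 0.7
    power: int = 1

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if int(self.power) != self.power or self.power < 1:
            raise ValueError("power must be a positive integer")


@dataclass(frozen=True)
class Tether:
    """Harmonic restraint 0.5 k |x - center|^2 with lambda-interpolated k.

    k(lambda) = (1-lam) k_a + lam k_b, in kJ mol^-1 nm^-2.  Setting
    k_a == k_b gives a lambda-independent tether.
    """

    center: tuple
    k_a: float
    k_b: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        if self.k_b is None:
            object.__setattr__(self, "k_b", self.k_a)
        if self.k_a <= 0 or self.k_b <= 0:
            raise ValueError("tether spring constants must be positive")

    def k(self, lam: float) -> float:
        return (1.0 - lam) * self.k_a + lam * self.k_b


def _plain_pair(r_a6, r_b6, lam, state_a, state_b):
    """Soft-core pair energy from the effective sixth-power radii."""
    va = state_a.c12 / r_a6**2 - state_a.c6 / r_a6
    va = va + F_COULOMB * state_a.q_i * state_a.q_j / r_a6 ** (1.0 / 6.0)
    vb = state_b.c12 / r_b6**2 - state_b.c6 / r_b6
    vb = vb + F_COULOMB * state_b.q_i * state_b.q_j / r_b6 ** (1.0 / 6.0)
    return (1.0 - lam) * va + lam * vb


def softcore_pair_energy(
    r,
    lam: float,
    state_a: NonbondedPairState,
    state_b: NonbondedPairState,
    sc: SoftCoreParams = SoftCoreParams(),
):
    """Soft-core coupled pair energy in kJ/mol at separation r (nm).

    Finite for all r >= 0 whenever 0 < lam < 1 and sc.alpha > 0; reduces
    exactly to the plain A-state (B-state) potential at lam = 0 (lam = 1)
    for r > 0.  Accepts scalar or array r.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("separation must be non-negative")
    r6 = r**6
    r_a6 = sc.alpha * state_a.sigma6 * lam**sc.power + r6
    r_b6 = sc.alpha * state_b.sigma6 * (1.0 - lam) ** sc.power + r6
    a_live = (1.0 - lam) != 0.0 and _state_nonzero(state_a)
    b_live = lam != 0.0 and _state_nonzero(state_b)
    if (a_live and np.any(r_a6 == 0.0)) or (b_live and np.any(r_b6 == 0.0)):
        raise ZeroDivisionError(
            "singular pair energy: r = 0 with vanishing soft-core radius "
            "(alpha = 0 or endpoint lambda)"
        )
    # dead end states may still have r_x6 == 0; substitute 1 to avoid 0/0
    r_a6 = np.where(r_a6 == 0.0, 1.0, r_a6)
    r_b6 = np.where(r_b6 == 0.0, 1.0, r_b6)
    out = _plain_pair(r_a6, r_b6, lam, state_a, state_b)
    return float(out) if out.ndim == 0 else out


def _state_nonzero(state: NonbondedPairState) -> bool:
    return state.c6 != 0 or state.c12 != 0 or state.q_i * state.q_j != 0


def _softcore_pair_dhdl(r6, lam, state_a, state_b, sc):
    """Analytic d/dlam of the soft-core pair energy at fixed coordinates."""
    a6a = sc.alpha * state_a.sigma6
    a6b = sc.alpha * state_b.sigma6
    p = sc.power
    r_a6 = a6a * lam**p + r6
    r_b6 = a6b * (1.0 - lam) ** p + r6
    # d r_x^6 / d lam
    dra6 = a6a * p * lam ** (p - 1) if p > 1 or a6a != 0 else 0.0
    drb6 = -a6b * p * (1.0 - lam) ** (p - 1) if p > 1 or a6b != 0 else 0.0
    fa = F_COULOMB * state_a.q_i * state_a.q_j
    fb = F_COULOMB * state_b.q_i * state_b.q_j
    va = state_a.c12 / r_a6**2 - state_a.c6 / r_a6 + fa / r_a6 ** (1.0 / 6.0)
    vb = state_b.c12 / r_b6**2 - state_b.c6 / r_b6 + fb / r_b6 ** (1.0 / 6.0)
    # d V_X / d(r_x^6)
    dva = (
        -2.0 * state_a.c12 / r_a6**3
        + state_a.c6 / r_a6**2
        - fa / 6.0 * r_a6 ** (-7.0 / 6.0)
    )
    dvb = (
        -2.0 * state_b.c12 / r_b6**3
        + state_b.c6 / r_b6**2
        - fb / 6.0 * r_b6 ** (-7.0 / 6.0)
    )
    return -va + vb + (1.0 - lam) * dva * dra6 + lam * dvb * drb6


@dataclass(frozen=True)
class ToyAlchemicalSystem:
    """A few tethered particles with lambda-coupled pair interactions.

    pairs maps (i, j) with i < j to an (A-state, B-state) tuple of
    NonbondedPairState.  Every particle carries a Tether so that all
    configuration integrals are finite.
    """

    dimensionality: int
    tethers: tuple
    pairs: dict = field(default_factory=dict)
    softcore: SoftCoreParams = SoftCoreParams()
    temperature: float = 300.0

    def __post_init__(self):
        if not 1 <= self.dimensionality <= 3:
            raise ValueError("dimensionality must be 1, 2 or 3")
        object.__setattr__(self, "tethers", tuple(self.tethers))
        if not self.tethers:
            raise ValueError("every particle needs a tether")
        if len(self.tethers) > 4:
            raise ValueError("at most 4 particles")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        for te in self.tethers:
            if len(te.center) != self.dimensionality:
                raise ValueError("tether center dimensionality mismatch")
        for (i, j), states in self.pairs.items():
            if not (0 <= i < j < self.n_particles):
                raise ValueError(f"bad pair index ({i}, {j})")
            if len(states) != 2:
                raise ValueError("each pair needs both A and B states")

    @property
    def n_particles(self) -> int:
        return len(self.tethers)

    @property
    def n_dof(self) -> int:
        return self.n_particles * self.dimensionality

    # coords: array (..., n_particles, dim); vectorized over leading axes
    def potential(self, coords, lam: float):
        """Total potential energy in kJ/mol at fixed coordinates."""
        x = np.asarray(coords, dtype=float)
        e = np.zeros(x.shape[:-2])
        for p, te in enumerate(self.tethers):
            d = x[..., p, :] - np.asarray(te.center)
            e = e + 0.5 * te.k(lam) * np.sum(d * d, axis=-1)
        for (i, j), (sa, sb) in self.pairs.items():
            r = np.sqrt(np.sum((x[..., i, :] - x[..., j, :]) ** 2, axis=-1))
            e = e + softcore_pair_energy(r, lam, sa, sb, self.softcore)
        return float(e) if e.ndim == 0 else e

    def dhdl(self, coords, lam: float):
        return dhdl_analytic(self, coords, lam)


def dhdl_analytic(system: ToyAlchemicalSystem, coords, lam: float):
    """Analytic dH/dlam (kJ/mol) of the full Hamiltonian at fixed coords."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    x = np.asarray(coords, dtype=float)
    out = np.zeros(x.shape[:-2])
    for p, te in enumerate(system.tethers):
        d = x[..., p, :] - np.asarray(te.center)
        out = out + 0.5 * (te.k_b - te.k_a) * np.sum(d * d, axis=-1)
    for (i, j), (sa, sb) in system.pairs.items():
        r6 = np.sum((x[..., i, :] - x[..., j, :]) ** 2, axis=-1) ** 3
        out = out + _softcore_pair_dhdl(r6, lam, sa, sb, system.softcore)
    return float(out) if out.ndim == 0 else out


def mc_sample_dhdl(
    system: ToyAlchemicalSystem,
    lam: float,
    n_steps: int,
    step_size: float | None = None,
    seed: int = 0,
    stride: int = 1,
    n_warmup: int | None = None,
    dt: float = 1.0,
    replica_id: int | None = None,
) -> DhdlSeries:
    """Metropolis sampling of the lambda-ensemble, recording dH/dlambda.

    Single-particle uniform displacement moves at system.temperature.  The
    step size is auto-tuned during a discarded warm-up toward 40-60%
    acceptance.  The returned series is bit-reproducible for a fixed seed.
    Raises SamplingError if no production move is accepted.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be positive")
    rng = np.random.default_rng(seed)
    beta = 1.0 / (R_GAS * system.temperature)
    n_p, dim = system.n_particles, system.dimensionality
    x = np.array([te.center for te in system.tethers], dtype=float)
    # start each particle at its tether center, nudged off exact overlap
    x += 0.01 * rng.standard_normal(x.shape)
    e = system.potential(x, lam)
    step = 0.3 if step_size is None else float(step_size)
    if n_warmup is None:
        n_warmup = max(500, n_steps // 5)

    def sweep(n, step, tune):
        nonlocal x, e
        accepted = 0
        recorded = []
        acc_window = 0
        for s in range(n):
            p = rng.integers(n_p)
            move = step * rng.uniform(-1.0, 1.0, size=dim)
            x_new = x.copy()
            x_new[p] += move
            e_new = system.potential(x_new, lam)
            if e_new <= e or rng.random() < np.exp(-beta * (e_new - e)):
                x, e = x_new, e_new
                accepted += 1
                acc_window += 1
            if tune and (s + 1) % 100 == 0:
                frac = acc_window / 100.0
                if not 0.4 <= frac <= 0.6:
                    # proportional nudge toward 50% acceptance
                    step *= float(np.clip(frac / 0.5, 0.5, 2.0))
                    step = float(np.clip(step, 1e-4, 10.0))
                acc_window = 0
            if not tune and (s + 1) % stride == 0:
                recorded.append(dhdl_analytic(system, x, lam))
        return accepted, step, recorded

    _, step, _ = sweep(n_warmup, step, tune=True)
    accepted, _, recorded = sweep(n_steps, step, tune=False)
    if accepted == 0:
        raise SamplingError(
            f"Metropolis chain at lambda={lam} accepted no moves in "
            f"{n_steps} steps (step size {step:.3g} nm)"
        )
    values = np.array(recorded)
    times = dt * np.arange(1, len(values) + 1)
    series = DhdlSeries(
        lam=lam,
        replica_id=seed if replica_id is None else replica_id,
        times=times,
        values=values,
    )
    object.__setattr__(series, "acceptance_ratio", accepted / n_steps)
    return series


def _quadrature_grid(system: ToyAlchemicalSystem, n_grid: int, extent: float):
    """Per-degree-of-freedom 1D grids covering the tether wells."""
    axes = []
    rt_ = R_GAS * system.temperature
    for te in system.tethers:
        k_min = min(te.k_a, te.k_b)
        half = extent * np.sqrt(rt_ / k_min)
        for c in te.center:
            axes.append(np.linspace(c - half, c + half, n_grid))
    return axes


def _boltzmann_on_grid(system, lam, axes):
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack(mesh, axis=-1)  # (..., n_dof)
    coords = pts.reshape(pts.shape[:-1] + (system.n_particles, system.dimensionality))
    v = system.potential(coords, lam)
    if not np.all(np.isfinite(v)):
        raise FloatingPointError("non-finite potential on quadrature grid")
    v0 = np.min(v)
    return coords, np.exp(-(v - v0) / (R_GAS * system.temperature)), v0


def _log_z(system, lam, axes):
    _, w, v0 = _boltzmann_on_grid(system, lam, axes)
    for ax in reversed(axes):
        w = np.trapezoid(w, ax, axis=-1)
    return np.log(w) - v0 / (R_GAS * system.temperature)


def exact_delta_g(
    system: ToyAlchemicalSystem, n_grid: int = 401, extent: float = 8.0
) -> float:
    """Exact dG = -RT ln(Z1/Z0) by dense configuration-integral quadrature.

    Feasible for n_particles x dimensionality <= 3 (dense tensor grid).
    ``extent`` is the half-width of each coordinate grid in units of the
    tether's thermal width sqrt(RT/k).
    """
    if system.n_dof > 3:
        raise ValueError(
            f"dense quadrature impractical for {system.n_dof} degrees of freedom"
        )
    axes = _quadrature_grid(system, n_grid, extent)
    rt_ = R_GAS * system.temperature
    return float(-rt_ * (_log_z(system, 1.0, axes) - _log_z(system, 0.0, axes)))


def exact_dhdl_mean(
    system: ToyAlchemicalSystem, lam: float, n_grid: int = 401, extent: float = 8.0
) -> float:
    """Exact lambda-ensemble average <dH/dlam> by quadrature (oracle)."""
    if system.n_dof > 3:
        raise ValueError("dense quadrature impractical beyond 3 degrees of freedom")
    axes = _quadrature_grid(system, n_grid, extent)
    coords, w, _ = _boltzmann_on_grid(system, lam, axes)
    num = w * dhdl_analytic(system, coords, lam)
    den = w
    for ax in reversed(axes):
        num = np.trapezoid(num, ax, axis=-1)
        den = np.trapezoid(den, ax, axis=-1)
    return float(num / den)
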