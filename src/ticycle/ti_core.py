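"""Thermodynamic-integration estimator.

The free-energy change of an alchemical transformation is

    dG = integral_0^1 < dH/dlambda >_lambda  dlambda,

estimated from per-lambda, per-replica time series of the Hamiltonian
derivative: each series is truncated to its equilibrated tail, replicas are
pooled into a per-lambda mean with a block-averaged standard error, and the
mean curve is integrated over the lambda schedule with the generalized
Simpson rule for non-equidistant nodes.  Statistical errors are propagated
through the quadrature weights treating lambda points as independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "DhdlSeries",
    "LambdaSchedule",
    "LambdaPointEstimate",
    "FreeEnergyEstimate",
    "parse_xvg",
    "discard_equilibration",
    "block_sem",
    "combine_replicas",
    "build_lambda_schedule",
    "simpson_nonuniform",
    "quadrature_weights",
    "estimate_free_energy",
    "protocol_accounting",
]

#: Default extra lambda nodes near the schedule ends (quartering the first
#: and last uniform interval of the 21-point grid).
DEFAULT_END_OFFSETS = (0.0125, 0.0375)


class XvgParseError(ValueError):
    """Raised when a dH/dl file cannot be parsed."""


@dataclass(frozen=True)
class DhdlSeries:
    """One replica's dH/dlambda time series at a fixed lambda.

    Attributes
    ----------
    lam : coupling parameter in [0, 1].
    replica_id : integer label of the independent simulation.
    times : sampling times in ps, strictly increasing.
    values : dH/dlambda in kJ/mol, one per time.
    """

    lam: float
    replica_id: int
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {self.lam}")
        if t.ndim != 1 or v.ndim != 1 or len(t) != len(v) or len(t) < 1:
            raise ValueError("times and values must be 1-D, equal length, non-empty")
        if np.any(t < 0):
            raise ValueError("times must be non-negative")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class LambdaSchedule:
    """Ordered distinct lambda nodes spanning [0, 1]."""

    nodes: np.ndarray

    def __post_init__(self):
        nodes = np.asarray(self.nodes, dtype=float)
        object.__setattr__(self, "nodes", nodes)
        if nodes.ndim != 1 or len(nodes) < 2:
            raise ValueError("schedule needs at least two nodes")
        if nodes[0] != 0.0 or nodes[-1] != 1.0:
            raise ValueError("schedule must start at 0 and end at 1")
        if np.any(np.diff(nodes) <= 0):
            raise ValueError("schedule nodes must be strictly increasing")

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self):
        return iter(self.nodes)


@dataclass(frozen=True)
class LambdaPointEstimate:
    """Per-lambda ensemble mean of dH/dlambda with its standard error."""

    lam: float
    mean: float
    sem: float
    n_replicas: int
    n_samples_used: int

    def __post_init__(self):
        if self.sem < 0:
            raise ValueError("sem must be non-negative")
        if self.n_replicas < 1:
            raise ValueError("need at least one replica")


@dataclass(frozen=True)
class FreeEnergyEstimate:
    """dG of one alchemical leg with quadrature-propagated error."""

    delta_g: float
    sigma: float
    schedule: LambdaSchedule
    points: tuple[LambdaPointEstimate, ...] = field(default=())

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def to_dict(self) -> dict:
        return {
            "delta_g_kj_mol": self.delta_g,
            "sigma_kj_mol": self.sigma,
            "lambda_nodes": list(map(float, self.schedule.nodes)),
            "per_lambda": [
                {
                    "lambda": p.lam,
                    "mean": p.mean,
                    "sem": p.sem,
                    "n_replicas": p.n_replicas,
                    "n_samples_used": p.n_samples_used,
                }
                for p in self.points
            ],
        }


def parse_xvg(path) -> DhdlSeries:
    """Read a two-column xvg-style dH/dlambda file.

    Lines starting with ``#`` are comments; ``@`` lines carry metadata, of
    which ``@ lambda <x>`` and ``@ replica <i>`` are recognized.  Data rows
    are ``time(ps)  value(kJ/mol)``.
    """
    path = Path(path)
    lam = None
    replica = 0
    times: list[float] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("@"):
                parts = line[1:].split()
                if len(parts) >= 2 and parts[0] == "lambda":
                    lam = float(parts[1])
                elif len(parts) >= 2 and parts[0] == "replica":
                    replica = int(parts[1])
                continue
            cols = line.split()
            try:
                t, v = float(cols[0]), float(cols[1])
            except (ValueError, IndexError) as exc:
                raise XvgParseError(
                    f"{path}:{lineno}: cannot parse data row {line!r}"
                ) from exc
            times.append(t)
            values.append(v)
    if not times:
        raise XvgParseError(f"{path}: no data rows found")
    return DhdlSeries(
        lam=lam if lam is not None else 0.0,
        replica_id=replica,
        times=np.array(times),
        values=np.array(values),
    )


def discard_equilibration(
    series: DhdlSeries, keep_last: float = 150.0, expected_span: float = 500.0
) -> DhdlSeries:
    """Drop the equilibration transient, keeping the last ``keep_last`` ps.

    Retains samples with time > t_end - keep_last, where t_end is the
    series' own final time, so truncated series degrade gracefully.  A
    series shorter than the window is returned whole with a warning.
    """
    t = series.times
    span = t[-1] - t[0]
    dt_est = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    if keep_last >= span:
        if keep_last > span + dt_est:
            warnings.warn(
                f"keep_last={keep_last} ps >= series span {span} ps at "
                f"lambda={series.lam}; returning full series",
                stacklevel=2,
            )
        return series
    if span + dt_est < expected_span - 1e-9:
        warnings.warn(
            f"series at lambda={series.lam} spans {span} ps "
            f"(< expected {expected_span} ps)",
            stacklevel=2,
        )
    mask = t > t[-1] - keep_last
    return DhdlSeries(
        lam=series.lam,
        replica_id=series.replica_id,
        times=t[mask],
        values=series.values[mask],
    )


def block_sem(values: Sequence[float]) -> float:
    """Standard error of the mean robust to autocorrelation.

    Flyvbjerg-Petersen blocking: repeatedly average adjacent pairs; at each
    level the naive SEM sqrt(var/n) is recorded.  The reported estimate is
    the first level whose SEM changed by less than 10% over two successive
    doublings (the plateau); if no plateau is found, the deepest level's
    estimate is returned.  For uncorrelated data this reduces to s/sqrt(n).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be 1-D")
    n = len(x)
    if n < 8:
        raise ValueError(f"need at least 8 samples to block-average, got {n}")
    if np.allclose(x, x[0]):
        return 0.0
    sems = []
    while len(x) >= 8:
        m = len(x)
        sems.append(float(np.std(x, ddof=1) / np.sqrt(m)))
        x = 0.5 * (x[: 2 * (m // 2) : 2] + x[1 : 2 * (m // 2) : 2])
    for i in range(2, len(sems)):
        d1 = abs(sems[i] - sems[i - 1]) / sems[i] if sems[i] else 0.0
        d2 = abs(sems[i - 1] - sems[i - 2]) / sems[i - 1] if sems[i - 1] else 0.0
        if d1 < 0.10 and d2 < 0.10:
            return sems[i]
    return sems[-1]


def combine_replicas(series_at_lambda: Sequence[DhdlSeries]) -> LambdaPointEstimate:
    """Pool independent replicas at one lambda into a single estimate.

    The mean pools all retained samples.  Two SEM estimates are formed:
    (i) within-replica block SEMs combined as sqrt(sum sem_i^2)/R, and
    (ii) the cross-replica scatter sd(replica means)/sqrt(R).  The larger
    of the two is reported (conservative).  A single replica degenerates
    to its block SEM.
    """
    if len(series_at_lambda) < 1:
        raise ValueError("need at least one replica series")
    lams = {s.lam for s in series_at_lambda}
    if len(lams) > 1:
        raise ValueError(f"replicas mix lambda values: {sorted(lams)}")
    lam = series_at_lambda[0].lam
    all_values = np.concatenate([s.values for s in series_at_lambda])
    mean = float(np.mean(all_values))
    r = len(series_at_lambda)
    within = np.array([block_sem(s.values) for s in series_at_lambda])
    sem_within = float(np.sqrt(np.sum(within**2)) / r)
    if r >= 2:
        rep_means = np.array([np.mean(s.values) for s in series_at_lambda])
        sem_scatter = float(np.std(rep_means, ddof=1) / np.sqrt(r))
        sem = max(sem_within, sem_scatter)
    else:
        sem = sem_within
    return LambdaPointEstimate(
        lam=lam,
        mean=mean,
        sem=sem,
        n_replicas=r,
        n_samples_used=len(all_values),
    )


def build_lambda_schedule(
    n_uniform: int = 21,
    extra_per_end: int = 2,
    end_offsets: Sequence[float] = DEFAULT_END_OFFSETS,
) -> LambdaSchedule:
    """Uniform lambda grid on [0, 1] plus extra nodes near both ends.

    The default is 21 uniform nodes with two extra nodes per end at offsets
    0.0125 and 0.0375 (mirrored near lambda = 1), 25 nodes in total.
    """
    if n_uniform < 2:
        raise ValueError("need at least 2 uniform nodes")
    if extra_per_end > len(end_offsets):
        raise ValueError(
            f"{extra_per_end} extra nodes per end requested but only "
            f"{len(end_offsets)} offsets given"
        )
    nodes = list(np.linspace(0.0, 1.0, n_uniform))
    for off in end_offsets[:extra_per_end]:
        if not 0.0 < off < 1.0:
            raise ValueError(f"end offset {off} outside (0, 1)")
        for candidate in (off, 1.0 - off):
            if any(abs(candidate - u) < 1e-12 for u in nodes):
                raise ValueError(
                    f"extra node {candidate} coincides with an existing node"
                )
            nodes.append(candidate)
    return LambdaSchedule(np.sort(np.array(nodes)))


def quadrature_weights(xs: Sequence[float]) -> np.ndarray:
    """Weights of the generalized Simpson rule on arbitrary sorted nodes.

    Consecutive interval pairs are integrated by the quadratic through
    their three nodes; a leftover final interval is integrated under the
    quadratic through the last three nodes, so the rule stays exact for
    quadratics on every layout (with only two nodes the trapezoid rule is
    all that is possible).  The weights satisfy
    sum(w * y) == simpson_nonuniform for every y, and sum(w) equals the
    span.
    """
    x = np.asarray(xs, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need at least two nodes")
    if np.any(np.diff(x) <= 0):
        raise ValueError("nodes must be strictly increasing and distinct")
    w = np.zeros_like(x)
    n_int = len(x) - 1
    i = 0
    while i + 2 <= n_int:
        h0 = x[i + 1] - x[i]
        h1 = x[i + 2] - x[i + 1]
        h = h0 + h1
        # exact integral of the Lagrange quadratic through the three nodes
        w[i] += h * (2 * h0 - h1) / (6 * h0)
        w[i + 1] += h**3 / (6 * h0 * h1)
        w[i + 2] += h * (2 * h1 - h0) / (6 * h1)
        i += 2
    if i < n_int:  # odd interval count: quadratic tail over the last interval
        if len(x) >= 3:
            h0 = x[-2] - x[-3]
            h1 = x[-1] - x[-2]
            w[-3] += -(h1**3) / (6 * h0 * (h0 + h1))
            w[-2] += h1 * (3 * h0 + h1) / (6 * h0)
            w[-1] += h1 * (3 * h0 + 2 * h1) / (6 * (h0 + h1))
        else:  # two nodes: trapezoid is the only option
            h = x[1] - x[0]
            w[0] += h / 2
            w[1] += h / 2
    return w


def simpson_nonuniform(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Generalized Simpson quadrature for non-equidistant nodes.

    Exact for quadratics on any node layout; equals the classic composite
    Simpson rule on uniform grids with an even interval count.
    """
    y = np.asarray(ys, dtype=float)
    w = quadrature_weights(xs)
    if len(y) != len(w):
        raise ValueError("xs and ys must have equal length")
    return float(np.dot(w, y))


def estimate_free_energy(
    points: Sequence[LambdaPointEstimate], schedule: LambdaSchedule
) -> FreeEnergyEstimate:
    """Integrate per-lambda means over the schedule, propagating errors.

    dG = sum_i w_i * mean_i and sigma = sqrt(sum_i w_i^2 sem_i^2), with
    lambda points treated as statistically independent (separate
    simulations per lambda).
    """
    by_lam = {}
    for p in points:
        by_lam[round(p.lam, 12)] = p
    missing = [
        float(node) for node in schedule.nodes if round(float(node), 12) not in by_lam
    ]
    if missing:
        raise ValueError(f"no estimate at lambda values: {missing}")
    ordered = tuple(by_lam[round(float(node), 12)] for node in schedule.nodes)
    w = quadrature_weights(schedule.nodes)
    means = np.array([p.mean for p in ordered])
    sems = np.array([p.sem for p in ordered])
    delta_g = float(np.dot(w, means))
    sigma = float(np.sqrt(np.sum(w**2 * sems**2)))
    return FreeEnergyEstimate(delta_g=delta_g, sigma=sigma, schedule=schedule, points=ordered)


def protocol_accounting(
    schedule: LambdaSchedule, n_replicas: int, t_per_replica: float
) -> float:
    """Total simulated time in ns: nodes x replicas x ps-per-replica."""
    if n_replicas < 1 or t_per_replica <= 0:
        raise ValueError("n_replicas and t_per_replica must be positive")
    return len(schedule) * n_replicas * t_per_replica / 1000.0
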