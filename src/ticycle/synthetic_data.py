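"""Synthetic inputs with known ground truth.

Two families of fixtures:

* AR(1) surrogate dH/dlambda series: a smooth polynomial mean curve
  g(lambda) plus stationary first-order autoregressive noise, emulating the
  statistical structure of production Hamiltonian-derivative traces (smooth
  ensemble mean, autocorrelated fluctuations).  The exact integral of g is
  available in closed form, so estimator recovery can be scored against
  truth.

* Toy structures and trajectories with planted hydrogen bonds, salt-bridge
  contacts at stated separations, and Gaussian positional jitter of known
  amplitude, used to validate the interface metrics.  These fixtures are
  geometric/statistical, not physical.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter
from scipy.spatial.transform import Rotation

from .minipdb import StructureFrame, write_minipdb
from .ti_core import DhdlSeries

__all__ = [
    "SurrogateSpec",
    "PlantedRecipe",
    "PlantedStructure",
    "gen_ar1_dhdl",
    "true_integral",
    "write_dhdl_xvg",
    "gen_planted_structure",
    "gen_fluctuating_trajectory",
    "write_minipdb",
]


@dataclass(frozen=True)
class SurrogateSpec:
    """Recipe for AR(1) surrogate dH/dlambda studies.

    coeffs are ascending-power polynomial coefficients of the true mean
    curve g(lambda) in kJ/mol; sigma_n is the innovation standard
    deviation, phi the AR(1) coefficient (stationary variance
    sigma_n^2/(1-phi^2), lag-k autocorrelation phi^k).
    """

    coeffs: tuple = (0.0,)
    sigma_n: float = 5.0
    phi: float = 0.8
    dt: float = 1.0
    n_steps: int = 500
    n_replicas: int = 9
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "coeffs", tuple(float(c) for c in self.coeffs))
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("polynomial coefficients must be finite")
        if not 0.0 <= abs(self.phi) < 1.0:
            raise ValueError("|phi| must be < 1 for stationarity")
        if self.sigma_n < 0:
            raise ValueError("sigma_n must be non-negative")
        if self.n_steps < 1 or self.n_replicas < 1:
            raise ValueError("n_steps and n_replicas must be positive")

    def g(self, lam):
        """True mean curve g(lambda) in kJ/mol."""
        return np.polynomial.polynomial.polyval(lam, np.asarray(self.coeffs))


def _replica_rng(spec: SurrogateSpec, lam: float, replica: int):
    # replica r keys off master + r; the lambda key decorrelates lambda points
    return np.random.default_rng([spec.seed + replica, int(round(lam * 10**8))])


def gen_ar1_dhdl(spec: SurrogateSpec, lam: float) -> list[DhdlSeries]:
    """All replicas' surrogate series at one lambda point.

    Each series is g(lambda) plus stationary AR(1) noise: the first
    deviation is drawn from the stationary distribution, so closed-form
    variance checks hold from the first sample.  Replicas are independent.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    mean = float(spec.g(lam))
    n = spec.n_steps
    # sample at the end of each interval: n steps of dt end at n*dt
    times = spec.dt * np.arange(1, n + 1)
    out = []
    for r in range(spec.n_replicas):
        rng = _replica_rng(spec, lam, r)
        if spec.sigma_n == 0.0:
            dev = np.zeros(n)
        else:
            sd_stat = spec.sigma_n / np.sqrt(1.0 - spec.phi**2)
            dev = np.empty(n)
            dev[0] = sd_stat * rng.standard_normal()
            if n > 1:
                eps = spec.sigma_n * rng.standard_normal(n - 1)
                dev[1:], _ = lfilter(
                    [1.0], [1.0, -spec.phi], eps, zi=np.array([spec.phi * dev[0]])
                )
        out.append(
            DhdlSeries(lam=lam, replica_id=r, times=times, values=mean + dev)
        )
    return out


def true_integral(spec: SurrogateSpec) -> float:
    """Exact integral_0^1 g(lambda) dlambda by term-wise antiderivative."""
    poly = np.polynomial.polynomial.Polynomial(np.asarray(spec.coeffs))
    anti = poly.integ()
    return float(anti(1.0) - anti(0.0))


def write_dhdl_xvg(series: DhdlSeries, path) -> None:
    """Write one series in the two-column xvg-style dialect.

    Values are printed with 17 significant digits so the file round-trips
    bit-exactly through ti_core.parse_xvg.
    """
    if len(series) < 1:
        raise ValueError("cannot write an empty series")
    with open(path, "w") as fh:
        fh.write("# dH/dlambda time series (ticycle synthetic dialect)\n")
        fh.write('@ title "dH/dl"\n')
        fh.write(f"@ lambda {float(series.lam):.17g}\n")
        fh.write(f"@ replica {series.replica_id}\n")
        fh.write('@ xaxis label "Time (ps)"\n')
        fh.write('@ yaxis label "dH/dl (kJ/mol)"\n')
        for t, v in zip(series.times, series.values):
            fh.write(f"{float(t):.17g} {float(v):.17g}\n")


# ---------------------------------------------------------------------------
# planted structures

#: well-separated unit rays: upper hemisphere for charge partners,
#: lower hemisphere for hydrogen-bond complexes
_UPPER_RAYS = np.array(
    [
        [0.0, 0.0, 1.0],
        [0.940, 0.0, 0.342],
        [-0.470, 0.814, 0.342],
        [-0.470, -0.814, 0.342],
        [0.575, 0.575, 0.582],
        [-0.575, 0.575, 0.582],
    ]
)
_UPPER_RAYS /= np.linalg.norm(_UPPER_RAYS, axis=1, keepdims=True)
_LOWER_RAYS = _UPPER_RAYS * np.array([1.0, 1.0, -1.0])

#: hub of the donor cluster, away from the charged group at the origin
_DONOR_HUB_RADIUS = 0.9
#: covalent donor-hydrogen bond length, nm
_DH_BOND = 0.10


@dataclass(frozen=True)
class PlantedRecipe:
    """Counts and separations of the interactions to plant.

    opposite_charge_nm: minimum-atom distances (nm) of oppositely charged
    partner groups from the center residue's charged group.
    like_charge_nm: decoy partners with the same sign (never counted).
    hbond_nm: donor-acceptor distances of ideal linear D-H...A bonds
    donated by the center residue.
    bent_hbond: (distance nm, H-D-A angle deg) decoys violating the
    angular criterion.
    """

    opposite_charge_nm: tuple = ()
    like_charge_nm: tuple = ()
    hbond_nm: tuple = ()
    bent_hbond: tuple = ()  # (distance_nm, angle_deg) pairs


@dataclass
class PlantedStructure:
    """A generated frame plus the manifest of what was planted."""

    frame: StructureFrame
    center_residue_id: int
    hbond_count: int
    hbond_distances: tuple
    contact_distances: tuple  # (distance, partner formal charge sign)
    like_charge_distances: tuple

    def expected_contacts(self, cutoff: float) -> int:
        """Planted opposite-charge partners within ``cutoff`` (cumulative)."""
        return sum(1 for d in self.contact_distances if d <= cutoff)


def gen_planted_structure(
    recipe: PlantedRecipe, seed: int = 0, center_charge: float = 1.0
) -> PlantedStructure:
    """Build a structure whose interaction counts are known by construction.

    The center residue (id 1, LYS-like) carries a +1 charged group (atom
    NZ) at the origin and one donor N-H per requested hydrogen bond on a
    hub 0.9 nm below.  Partner residues sit on well-separated rays so no
    unplanned interaction can satisfy the default geometric criteria.
    Manifest distances match coordinates to 1e-6 nm.
    """
    n_charge = len(recipe.opposite_charge_nm) + len(recipe.like_charge_nm)
    n_hb = len(recipe.hbond_nm) + len(recipe.bent_hbond)
    if n_charge > len(_UPPER_RAYS):
        raise ValueError(f"at most {len(_UPPER_RAYS)} charge partners supported")
    if n_hb > len(_LOWER_RAYS):
        raise ValueError(f"at most {len(_LOWER_RAYS)} hydrogen bonds supported")
    for d in (*recipe.opposite_charge_nm, *recipe.like_charge_nm):
        if not 0.15 < d < 2.0:
            raise ValueError(f"charge-contact distance {d} nm infeasible")
    for d in (*recipe.hbond_nm, *(d for d, _ in recipe.bent_hbond)):
        if not _DH_BOND + 0.02 < d < 0.8:
            raise ValueError(f"hydrogen-bond distance {d} nm infeasible")

    names, resnames, resids, charges, coords = [], [], [], [], []

    def add(name, resname, resid, q, xyz):
        names.append(name)
        resnames.append(resname)
        resids.append(resid)
        charges.append(q)
        coords.append(np.asarray(xyz, dtype=float))

    # center residue: charged group at the origin
    add("NZ", "LYS", 1, center_charge, (0.0, 0.0, 0.0))
    add("CE", "LYS", 1, 0.0, (0.0, 0.15, 0.0))

    next_resid = 2
    contact_distances = []
    ray_iter = iter(_UPPER_RAYS)
    for d in recipe.opposite_charge_nm:
        u = next(ray_iter)
        add("OE1", "GLU", next_resid, -0.5, d * u)
        add("OE2", "GLU", next_resid, -0.5, (d + 0.22) * u)
        contact_distances.append(float(d))
        next_resid += 1
    like_distances = []
    for d in recipe.like_charge_nm:
        u = next(ray_iter)
        add("NH1", "ARG", next_resid, 0.5, d * u)
        add("NH2", "ARG", next_resid, 0.5, (d + 0.22) * u)
        like_distances.append(float(d))
        next_resid += 1

    hbond_distances = []
    ray_iter = iter(_LOWER_RAYS)
    for k, d in enumerate(recipe.hbond_nm, start=1):
        v = np.asarray(next(ray_iter))
        n_pos = _DONOR_HUB_RADIUS * v
        add(f"ND{k}", "LYS", 1, 0.0, n_pos)
        add(f"HD{k}", "LYS", 1, 0.0, n_pos + _DH_BOND * v)  # linear D-H...A
        add("OG", "SER", next_resid, 0.0, n_pos + d * v)
        hbond_distances.append(float(d))
        next_resid += 1
    for k, (d, angle_deg) in enumerate(recipe.bent_hbond, start=1):
        v = np.asarray(next(ray_iter))
        n_pos = _DONOR_HUB_RADIUS * v
        # hydrogen rotated off the D->A axis by the requested angle
        perp = np.cross(v, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(v, [1.0, 0.0, 0.0])
        perp /= np.linalg.norm(perp)
        ang = np.radians(angle_deg)
        h_dir = np.cos(ang) * v + np.sin(ang) * perp
        add(f"NB{k}", "LYS", 1, 0.0, n_pos)
        add(f"HB{k}", "LYS", 1, 0.0, n_pos + _DH_BOND * h_dir)
        add("OG", "SER", next_resid, 0.0, n_pos + d * v)
        next_resid += 1

    frame = StructureFrame(
        names=np.array(names),
        residue_ids=np.array(resids, dtype=int),
        residue_names=np.array(resnames),
        charges=np.array(charges, dtype=float),
        coords=np.stack(coords),
    )
    return PlantedStructure(
        frame=frame,
        center_residue_id=1,
        hbond_count=len(recipe.hbond_nm),
        hbond_distances=tuple(hbond_distances),
        contact_distances=tuple(contact_distances),
        like_charge_distances=tuple(like_distances),
    )


def gen_fluctuating_trajectory(
    structure: PlantedStructure | StructureFrame,
    sigma_a: float,
    n_frames: int,
    seed: int = 0,
    rigid_motion: bool = False,
) -> list[StructureFrame]:
    """Frames of isotropic Gaussian jitter about the reference structure.

    Each coordinate receives independent N(0, sigma_a^2) noise, so the
    population per-atom RMSF is sigma_a * sqrt(3).  With
    ``rigid_motion=True`` every frame is additionally rotated and
    translated at random, which a Kabsch fit must remove.
    """
    if sigma_a < 0:
        raise ValueError("sigma_a must be non-negative")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    frame = structure.frame if isinstance(structure, PlantedStructure) else structure
    rng = np.random.default_rng(seed)
    ref = frame.coords
    frames = []
    for _ in range(n_frames):
        xyz = ref + sigma_a * rng.standard_normal(ref.shape)
        if rigid_motion:
            rot = Rotation.random(rng=rng).as_matrix()
            shift = rng.uniform(-2.0, 2.0, size=3)
            xyz = xyz @ rot.T + shift
        frames.append(frame.with_coords(xyz))
    return frames
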