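"""End-to-end study orchestration: generate, estimate, close the cycle.

The functions here are what the CLI subcommands call; they are equally
usable from Python.
"""

from __future__ import annotations

import json
from pathlib import Path

from . import synthetic_data, thermo_cycle, ti_core
from .config import LEG_NAMES, RunConfig
from .synthetic_data import SurrogateSpec

__all__ = [
    "synth_study",
    "estimate_leg",
    "estimate_all_legs",
    "run_cycle",
    "leg_surrogate_spec",
]

#: deterministic per-leg master-seed offsets (well below 2^31 combined)
_LEG_SEED_OFFSET = {name: 10_000 * (i + 1) for i, name in enumerate(LEG_NAMES)}


def leg_surrogate_spec(config: RunConfig, leg: str) -> SurrogateSpec:
    spec = config.legs[leg]
    return SurrogateSpec(
        coeffs=spec.coeffs,
        sigma_n=spec.sigma_n,
        phi=spec.phi,
        dt=config.dt_ps,
        n_steps=config.n_steps,
        n_replicas=config.n_replicas,
        seed=config.seed + _LEG_SEED_OFFSET[leg],
    )


def synth_study(config: RunConfig, outdir, force: bool = False) -> dict:
    """Write a complete synthetic study: legs x lambda nodes x replicas.

    Returns the ground-truth manifest (also written as manifest.json).
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty (use force)")
    schedule = config.schedule()
    manifest = {"legs": {}, "n_files": 0}
    for leg in config.legs:
        spec = leg_surrogate_spec(config, leg)
        leg_dir = outdir / leg
        leg_dir.mkdir(parents=True, exist_ok=True)
        for i, lam in enumerate(schedule):
            for series in synthetic_data.gen_ar1_dhdl(spec, float(lam)):
                path = leg_dir / f"dhdl_l{i:02d}_r{series.replica_id}.xvg"
                synthetic_data.write_dhdl_xvg(series, path)
                manifest["n_files"] += 1
        manifest["legs"][leg] = {
            "true_delta_g": synthetic_data.true_integral(spec),
            "coeffs": list(spec.coeffs),
            "sigma_n": spec.sigma_n,
            "phi": spec.phi,
            "seed": spec.seed,
        }
    legs = manifest["legs"]
    if {"dimer", "monomer"} <= legs.keys():
        manifest["true_ddg_dimerization"] = (
            legs["dimer"]["true_delta_g"] - 2 * legs["monomer"]["true_delta_g"]
        )
    if {"monomer", "unfolded"} <= legs.keys():
        manifest["true_ddg_folding"] = (
            legs["monomer"]["true_delta_g"] - legs["unfolded"]["true_delta_g"]
        )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def estimate_leg(
    leg_dir, config: RunConfig, schedule=None
) -> ti_core.FreeEnergyEstimate:
    """Parse one leg's series files and run the full TI estimator."""
    leg_dir = Path(leg_dir)
    schedule = config.schedule() if schedule is None else schedule
    files = sorted(leg_dir.glob("*.xvg"))
    if not files:
        raise FileNotFoundError(f"no .xvg series files in {leg_dir}")
    by_lambda: dict[float, list] = {}
    for path in files:
        series = ti_core.parse_xvg(path)
        trimmed = ti_core.discard_equilibration(
            series, config.keep_last_ps, config.t_per_replica_ps
        )
        by_lambda.setdefault(round(series.lam, 12), []).append(trimmed)
    missing = [
        float(lam) for lam in schedule if round(float(lam), 12) not in by_lambda
    ]
    if missing:
        raise ValueError(f"{leg_dir}: no series at lambda values {missing}")
    points = [ti_core.combine_replicas(group) for group in by_lambda.values()]
    return ti_core.estimate_free_energy(points, schedule)


def estimate_all_legs(study_dir, config: RunConfig) -> dict:
    study_dir = Path(study_dir)
    out = {}
    for leg in config.legs:
        out[leg] = estimate_leg(study_dir / leg, config)
    return out


def run_cycle(estimates: dict, config: RunConfig) -> dict:
    """Close the thermodynamic cycle and build the convergence report."""
    legs = thermo_cycle.CycleLegs(
        dg_dimer=estimates.get("dimer"),
        dg_monomer=estimates.get("monomer"),
        dg_unfolded=estimates.get("unfolded"),
        temperature=config.temperature,
    )
    result = thermo_cycle.cycle_result(legs, config.classification_multiplier)
    report = thermo_cycle.convergence_report(
        {name: est.points for name, est in estimates.items()},
        thresholds=config.sem_thresholds,
        temperature=config.temperature,
    )
    return {
        "legs": {name: est.to_dict() for name, est in estimates.items()},
        "ddg": result.to_dict(),
        "convergence": report.to_dict(),
    }
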