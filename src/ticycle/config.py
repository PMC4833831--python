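"""Run configuration: one structured YAML file drives a whole study.

Every field has a documented default matching the reference protocol
(25-node lambda schedule, 9 replicas of 500 ps, last 150 ps retained,
300 K).  CLI flags override config values; the config overrides the
built-in defaults.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .ti_core import LambdaSchedule, build_lambda_schedule

__all__ = ["LegSpec", "RunConfig", "load_config"]

#: legs of the thermodynamic cycle, in canonical order
LEG_NAMES = ("dimer", "monomer", "unfolded")


@dataclass(frozen=True)
class LegSpec:
    """Surrogate ground truth for one alchemical leg.

    coeffs define the true mean curve g(lambda) (ascending powers,
    kJ/mol); sigma_n and phi set the AR(1) noise.
    """

    coeffs: tuple = (0.0,)
    sigma_n: float = 5.0
    phi: float = 0.8


@dataclass(frozen=True)
class RunConfig:
    n_uniform: int = 21
    extra_per_end: int = 2
    end_offsets: tuple = (0.0125, 0.0375)
    n_replicas: int = 9
    t_per_replica_ps: float = 500.0
    dt_ps: float = 1.0
    keep_last_ps: float = 150.0
    temperature: float = 300.0
    seed: int = 2024
    sem_thresholds: tuple = (10.0, 20.0)
    classification_multiplier: float = 1.0
    legs: dict = field(
        default_factory=lambda: {
            "dimer": LegSpec(coeffs=(40.0, -30.0, 12.0), sigma_n=8.0, phi=0.8),
            "monomer": LegSpec(coeffs=(15.0, -12.0, 6.0), sigma_n=8.0, phi=0.8),
            "unfolded": LegSpec(coeffs=(5.0, -4.0, 3.0), sigma_n=8.0, phi=0.8),
        }
    )

    def schedule(self) -> LambdaSchedule:
        return build_lambda_schedule(
            self.n_uniform, self.extra_per_end, self.end_offsets
        )

    @property
    def n_steps(self) -> int:
        return int(round(self.t_per_replica_ps / self.dt_ps))

    def with_overrides(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs) if kwargs else self


def load_config(path=None, **overrides) -> RunConfig:
    """Read a YAML config file; missing fields fall back to defaults."""
    if path is None:
        return RunConfig().with_overrides(**overrides)
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    legs = raw.pop("legs", None)
    for key in ("end_offsets", "sem_thresholds"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = RunConfig(**raw)
    if legs is not None:
        parsed = {}
        for name, spec in legs.items():
            if name not in LEG_NAMES:
                raise ValueError(f"unknown leg {name!r}; expected one of {LEG_NAMES}")
            spec = dict(spec)
            if "coeffs" in spec:
                spec["coeffs"] = tuple(spec["coeffs"])
            parsed[name] = LegSpec(**spec)
        cfg = replace(cfg, legs=parsed)
    return cfg.with_overrides(**overrides)


def config_hash(path) -> str:
    """Short content hash of the config file, for run logs."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]
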