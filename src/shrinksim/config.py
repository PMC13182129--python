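"""Run configuration: a serialisable bundle of every knob a study run needs."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .dgm import COVARIANCE_MODES

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Configuration of one simulation run.

    Round-trips losslessly through YAML/JSON so a finished run's resolved
    configuration can be archived next to its outputs and replayed.
    """

    study: int = 1
    dgm: str = "default"                 # "default" | "independent_c"
    covariance_mode: str = "random_psd"  # "random_psd" | "identity"
    n_scenarios: int = 100
    iterations: int = 250
    validation_n: int = 1_000_000
    b_boot: int = 200
    master_seed: int = 0
    output_dir: str = "shrinksim_out"
    boot_failure_tol: float = 0.05
    n_cap: int = 100_000
    strata: list[float] = field(
        default_factory=lambda: [0.55, 0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9]
    )
    # simulation-based sample-size search (study 2)
    nsim_m_per_eval: int = 500
    nsim_validation_n: int = 100_000
    nsim_tolerance: float = 0.005
    nsim_max_evals: int = 40

    def validate(self) -> None:
        if self.study not in (1, 2):
            raise ValueError("study must be 1 or 2")
        if self.dgm not in ("default", "independent_c"):
            raise ValueError("dgm must be 'default' or 'independent_c'")
        if self.covariance_mode not in COVARIANCE_MODES:
            raise ValueError(f"covariance_mode must be one of {COVARIANCE_MODES}")
        for name in ("n_scenarios", "iterations", "validation_n", "b_boot",
                     "nsim_m_per_eval", "nsim_validation_n", "nsim_max_evals"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if sorted(self.strata) != list(self.strata):
            raise ValueError("strata edges must be increasing")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "RunConfig":
        return cls.from_dict(json.loads(s))
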