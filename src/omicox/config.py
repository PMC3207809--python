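"""Run configuration: every tunable default in one flat document.

A run is self-describing: the fully materialized configuration (defaults
included) is written next to every artifact together with its hash, and
unknown keys in a user-supplied config file are startup errors.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import yaml

__all__ = ["RunConfig", "config_hash"]


@dataclass
class RunConfig:
    # synthetic cohort
    n_samples: int = 481
    n_genes: int = 100
    n_mirnas: int = 20
    n_causal: int = 10
    causal_effect: float = 0.5
    rho_cna: float = 0.6
    rho_meth: float = -0.5
    rho_mirna: float = -0.3
    baseline_scale: float = 60.0
    censor_target: float = 0.45
    # integration
    cutoff_cna: float = 0.3
    cutoff_meth: float = 0.3
    cutoff_mirna: float = 0.2
    sign_policy: str = "any"
    max_missing: float = 0.2
    # split
    train_fraction: float = 0.8
    stratify_events: bool = False
    # path / CV
    lambda2: float = 1e-5
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-3
    cv_folds: int = 2
    cv_repeats: int = 10
    # quantile conventions
    tertile_low: float = 1 / 3
    tertile_high: float = 2 / 3
    rank_low_q: float = 0.15
    rank_high_q: float = 0.85
    # randomness
    seed: int = 0

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must be a flat key-value mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def config_hash(config: RunConfig | dict) -> str:
    data = config.to_dict() if isinstance(config, RunConfig) else dict(config)
    payload = json.dumps(data, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
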