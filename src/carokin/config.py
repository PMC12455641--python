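"""Run configuration for the pipeline CLI."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    network_path: str | None = None      # None = packaged default
    thermo_path: str | None = None
    level: str = "simple"
    scenario: str = "neutral"
    n_particles: int = 200
    cutoff: float = 0.05
    seed: int = 0
    erg9b_coeff: float = 0.025           # mmol/gDCW per unit growth rate
    flux_noise_sd: float = 0.1
    enzyme_noise_sd: float = 0.05
    max_nfev: int = 150
    imbalance_tol: float = 1e-6
    bootstrap_resamples: int = 1_000_000
    out_dir: str = "carokin_out"

    def validate(self) -> None:
        if self.level not in ("simple", "regulated", "detailed"):
            raise ConfigError(f"unknown structure level {self.level!r}")
        if not (0.0 < self.cutoff <= 1.0):
            raise ConfigError("cutoff must be in (0, 1]")
        if self.n_particles < 1:
            raise ConfigError("n_particles must be >= 1")
        for p in (self.network_path, self.thermo_path):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"referenced file does not exist: {p}")

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg
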