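"""Pipeline configuration: one versioned mapping holding every tunable
constant of the analysis, so sensitivity runs need no code change."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .fem import DEFAULT_BSI_SCALE

__all__ = ["PipelineConfig", "load_config"]

CONFIG_VERSION = 1


@dataclass
class PipelineConfig:
    version: int = CONFIG_VERSION
    seed: int = 0
    # cohort generation
    n_patients: int = 40
    n_female: int = 29
    n_male: int = 11
    effect_noise_sd: float = 0.02
    responder_fraction: float = 14 / 40
    # Auto-CM
    autocm_C: float | None = None  # None → number of variables
    autocm_tol: float = 1e-6
    autocm_max_epochs: int = 1000
    # graph
    hub_degree_threshold: int = 3
    max_extra: int | None = None
    # FEM / BSI
    morgan_a: float = 4730.0
    morgan_b: float = 1.56
    t_eff: float = 3.0
    load_c_w: float = 0.6
    load_h_ref: float = 1.70
    poisson_nu: float = 0.3
    bsi_scale: float = DEFAULT_BSI_SCALE
    # stats
    alpha: float = 0.05
    responder_threshold_pct: float = 10.0
    # HSA
    rho_m: float = 1.05
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.responder_threshold_pct <= 0:
            raise ValueError("responder threshold must be positive")
        if self.n_female + self.n_male != self.n_patients:
            raise ValueError("sex counts must sum to n_patients")
        if self.effect_noise_sd < 0:
            raise ValueError("effect_noise_sd must be non-negative")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def load_config(path=None, **overrides) -> PipelineConfig:
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
        if data.get("version", CONFIG_VERSION) != CONFIG_VERSION:
            raise ValueError(f"unsupported config version {data.get('version')}")
    data.update(overrides)
    known = {k: v for k, v in data.items() if k in PipelineConfig.__dataclass_fields__}
    cfg = PipelineConfig(**known)
    cfg.validate()
    return cfg
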