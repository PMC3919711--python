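"""Run configuration: schema-validated YAML/JSON configs and named presets
for the standard experiment setups.

A :class:`RunConfig` bundles everything a protocol run needs (cell constants,
network, target partition, noise, stimulus amplitude, solver and classifier
settings).  Unknown keys are rejected with a field-level message and a config
round-trips losslessly through ``to_dict`` / ``RunConfig(**d)``.
"""
from __future__ import annotations

from typing import List, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .network import build_adjacency, partition
from .params import CellParams, NoiseSpec


class CellConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    g_fast: float = 2.0
    g_slow: float = 2.0
    tau_m: float = 0.3
    tau_w_min: float = 5.0
    tau_w_max: float = 50.0
    k_tw: float = 0.2
    theta_tw: float = 0.16
    fast_shape: float = 0.3
    v_mid: float = 0.0
    v_scale: float = 0.28
    theta_slow: float = 0.16
    k_slow: float = 0.1
    w_floor: float = -0.425

    def build(self) -> CellParams:
        return CellParams(**self.model_dump())


class NetworkConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    N: int = 24
    topology: Literal["ring", "chain", "complete"] = "ring"
    n_cc: int = 2
    g_el: float = 0.02
    chain_renormalize: bool = False

    def build(self):
        return build_adjacency(self.N, self.topology, self.n_cc,
                               g_el=self.g_el,
                               chain_renormalize=self.chain_renormalize)


class NoiseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    sigma: float = 0.0
    update_dt: float = 0.2
    seed: int = 0

    def build(self) -> NoiseSpec:
        return NoiseSpec(**self.model_dump())


class StimulusConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    amplitude: float = 1.0
    duration: float = 0.2
    n_repeats: int = 3
    push_pull: bool = True


class SolverConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: Literal["rk4", "rk45"] = "rk4"
    h: float = 0.1
    rtol: float = 1e-6


class ClassifierConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    tol_phase: float = 0.02
    v_threshold: Optional[float] = None
    min_gap: float = 0.5
    transient_periods: float = 10.0


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    cell: CellConfig = Field(default_factory=CellConfig)
    network: NetworkConfig = Field(default_factory=NetworkConfig)
    group_sizes: Optional[List[int]] = None
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    stimulus: StimulusConfig = Field(default_factory=StimulusConfig)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    classifier: ClassifierConfig = Field(default_factory=ClassifierConfig)
    seed: int = 0
    out_dir: Optional[str] = None
    preset_name: Optional[str] = None

    @field_validator("group_sizes")
    @classmethod
    def _sizes_positive(cls, v):
        if v is not None and any(s <= 0 for s in v):
            raise ValueError("group sizes must be positive")
        return v

    def build_partition(self):
        sizes = self.group_sizes or [self.network.N // 2, self.network.N // 2]
        return partition(self.network.N, sizes)

    def to_dict(self) -> dict:
        return self.model_dump()


DEFAULTS_PATH = __file__.replace("config.py", "defaults.yaml")


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON) config file.

    An empty file yields all defaults (the benchmark parameter set).
    Unknown keys raise with the offending key named.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data)}")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


# --------------------------------------------------------------------------
# presets: parameters of the standard experiment setups
# --------------------------------------------------------------------------

_PRESETS = {
    # 2-phase (AP) in the fully coupled 24-cell network
    "fig1b1": dict(network=dict(N=24, topology="complete", n_cc=23,
                                g_el=0.12), group_sizes=[12, 12]),
    # 3-phase, same network
    "fig1b2": dict(network=dict(N=24, topology="complete", n_cc=23,
                                g_el=0.12), group_sizes=[8, 8, 8]),
    # 4-phase on the pure ring
    "fig2": dict(network=dict(N=24, topology="ring", n_cc=2, g_el=0.08),
                 group_sizes=[6, 6, 6, 6]),
    # stability-domain sweeps
    "fig3_24": dict(network=dict(N=24, topology="ring", n_cc=2, g_el=0.02),
                    noise=dict(sigma=0.002)),
    "fig3_60": dict(network=dict(N=60, topology="ring", n_cc=2, g_el=0.02),
                    noise=dict(sigma=0.002)),
    # 6-phase pattern at shortened duty cycle (tau_w_min is the one
    # parameter varied from the defaults; see docs/methods.md)
    "fig8_6phase": dict(network=dict(N=24, topology="ring", n_cc=2,
                                     g_el=0.08),
                        group_sizes=[4] * 6,
                        cell=dict(tau_w_min=2.0)),
    # asymmetric 2-phase, fully coupled
    "fig9": dict(network=dict(N=24, topology="complete", n_cc=23,
                              g_el=0.06), group_sizes=[22, 2]),
    "fig10_full": dict(network=dict(N=24, topology="complete", n_cc=23,
                                    g_el=0.02), noise=dict(sigma=0.002)),
    "fig10_ring": dict(network=dict(N=24, topology="ring", n_cc=2,
                                    g_el=0.02), noise=dict(sigma=0.002)),
    # chain comparison for the AP robustness increase
    "chain_ap": dict(network=dict(N=24, topology="chain", n_cc=2,
                                  g_el=0.02), group_sizes=[12, 12]),
}


def preset_names() -> list:
    return sorted(_PRESETS)


def preset(name: str) -> RunConfig:
    """Return the RunConfig with the printed parameters of a figure setup."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: "
                       f"{', '.join(preset_names())}")
    cfg = RunConfig(**_PRESETS[name])
    cfg.preset_name = name
    return cfg
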