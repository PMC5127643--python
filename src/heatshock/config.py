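"""Validated run configuration: YAML in, model objects out.

A :class:`RunConfig` bundles everything a reproducible run needs --
kinetic parameters, initial conditions, protocol, solver settings, and the
optional grid / phospho-gain / synthetic-dataset blocks. Unknown keys are
rejected, omitted keys fall back to the published defaults, and a config
round-trips through :func:`save_config` / :func:`load_config` unchanged.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .model import KineticParameters, ModelState, TemperatureMap
from .perturb import PhosphoGain
from .screen import FREE_PARAMETERS, ConstraintSpec, ParameterGrid

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Configuration file failed validation."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ParamsConfig(_Strict):
    k1: float = 166.8
    k2: float = 2.783
    k3: Optional[float] = None  # defaults to k1 (shared client on-rate)
    k4: float = 0.0464
    k5: float = 4.64e-7
    beta: float = 1.778
    Kd: float = 0.0022
    kdil: float = 0.0
    n: int = 3
    allow_unequal_on_rates: bool = False

    def build(self) -> KineticParameters:
        k3 = self.k1 if self.k3 is None else self.k3
        return KineticParameters(
            k1=self.k1, k2=self.k2, k3=k3, k4=self.k4, k5=self.k5,
            beta=self.beta, Kd=self.Kd, kdil=self.kdil, n=self.n,
            allow_unequal_on_rates=self.allow_unequal_on_rates,
        )


class InitConfig(_Strict):
    hsp_free: float = 1.0
    hsf1_free: float = 0.0
    up_free: float = 0.52
    hsp_hsf1: float = 1.0 / 500.0
    hsp_up: float = 0.0
    yfp: float = 3.0

    def build(self) -> ModelState:
        return ModelState(**self.model_dump())


class ProtocolConfig(_Strict):
    target_temp: float = 39.0
    basal_temp: float = 25.0
    duration: float = 120.0
    output_dt: float = Field(default=0.5, gt=0)


class SolverConfig(_Strict):
    method: Literal["LSODA", "Radau", "BDF", "RK45"] = "LSODA"
    rtol: float = Field(default=1e-6, gt=0)
    atol: float = Field(default=1e-9, gt=0)


class TemperatureMapConfig(_Strict):
    t_ref_low: float = 25.0
    up_ref_low: float = 0.52
    t_ref_high: float = 39.0
    up_ref_high: float = 10.51

    def build(self) -> TemperatureMap:
        return TemperatureMap(**self.model_dump())


class GridAxisConfig(_Strict):
    """Either an explicit value list or a min/max/count/scale range."""

    values: Optional[list[float]] = None
    min: Optional[float] = None
    max: Optional[float] = None
    count: int = 5
    scale: Literal["log", "linear"] = "log"

    def build(self) -> list[float]:
        import numpy as np

        if self.values is not None:
            return [float(v) for v in self.values]
        if self.min is None or self.max is None:
            raise ConfigError("grid axis needs either 'values' or 'min'+'max'")
        if self.scale == "log":
            return np.geomspace(self.min, self.max, self.count).tolist()
        return np.linspace(self.min, self.max, self.count).tolist()


class GridConfig(_Strict):
    k1: Optional[GridAxisConfig] = None
    k2: Optional[GridAxisConfig] = None
    k4: Optional[GridAxisConfig] = None
    k5: Optional[GridAxisConfig] = None
    beta: Optional[GridAxisConfig] = None
    Kd: Optional[GridAxisConfig] = None
    decades: float = 2.0  # bracket for axes left unspecified
    default_count: int = 5

    def build(self, center: KineticParameters) -> ParameterGrid:
        import numpy as np

        values = {}
        for name in FREE_PARAMETERS:
            axis: Optional[GridAxisConfig] = getattr(self, name)
            if axis is not None:
                values[name] = axis.build()
            else:
                c = getattr(center, name)
                values[name] = [
                    c * 10.0 ** e
                    for e in np.linspace(-self.decades, self.decades,
                                         self.default_count)
                ]
        return ParameterGrid(values=values)


class ConstraintConfig(_Strict):
    basal_bound_min: float = 0.5
    dissoc_threshold: float = 0.10
    dissoc_time: float = 5.0
    reassoc_threshold: float = 0.90
    reassoc_deadline: float = 60.0

    def build(self) -> ConstraintSpec:
        return ConstraintSpec(**self.model_dump())


class GainConfig(_Strict):
    beta_initial: float = 1.778
    beta_final: float = 3.556
    midpoint_time: float = 20.0
    steepness: float = 0.3

    def build(self) -> PhosphoGain:
        return PhosphoGain(**self.model_dump())


class SynthConfig(_Strict):
    kind: Literal["ipms_ratio", "yfp_median"] = "ipms_ratio"
    reps: int = 3
    noise_cv: Optional[float] = None  # kind-dependent default
    times: Optional[list[float]] = None
    temps: Optional[list[float]] = None

    def cv(self) -> float:
        if self.noise_cv is not None:
            return self.noise_cv
        return 0.15 if self.kind == "ipms_ratio" else 0.10


class RunConfig(_Strict):
    """Top-level validated configuration for any pipeline stage."""

    params: ParamsConfig = Field(default_factory=ParamsConfig)
    init: InitConfig = Field(default_factory=InitConfig)
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    temperature_map: TemperatureMapConfig = Field(default_factory=TemperatureMapConfig)
    grid: Optional[GridConfig] = None
    constraints: ConstraintConfig = Field(default_factory=ConstraintConfig)
    gain: GainConfig = Field(default_factory=GainConfig)
    synth: SynthConfig = Field(default_factory=SynthConfig)
    seed: int = 0

    def kinetic_parameters(self) -> KineticParameters:
        return self.params.build()

    def initial_state(self) -> ModelState:
        return self.init.build()


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config; omitted keys take the defaults.

    Raises :class:`FileNotFoundError` for a missing file and
    :class:`ConfigError` (listing the offending keys) for schema
    violations.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        keys = sorted(
            {".".join(str(p) for p in err["loc"]) or "<root>" for err in exc.errors()}
        )
        raise ConfigError(
            f"invalid config {path}: offending keys {keys}\n{exc}"
        ) from exc


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a config as YAML; ``load_config`` restores it exactly."""
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False)
    )
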