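"""YAML run configuration: geometry, design, true parameters, priors, MCMC."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from misbind.fit import McmcConfig, PopulationPrior
from misbind.forward import ModelParams
from misbind.taskgen import DesignSpec, TaskGeometry

__all__ = ["RunConfig", "load_config"]


def _build(cls, data: dict, where: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in config section {where!r}")
    return cls(**data)


@dataclass(frozen=True)
class RunConfig:
    """Everything a simulate/fit/recover run needs, from one YAML file."""

    geometry: TaskGeometry = field(default_factory=TaskGeometry)
    design: DesignSpec = field(default_factory=DesignSpec)
    population: ModelParams = field(default_factory=ModelParams.default)
    population_sd: float = 0.3
    prior: PopulationPrior = field(default_factory=PopulationPrior)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    variant: str = "full"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (unknown keys rejected)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    allowed = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown top-level config key(s) {sorted(unknown)}")

    kwargs = {}
    if "geometry" in raw:
        kwargs["geometry"] = _build(TaskGeometry, raw["geometry"], "geometry")
    if "design" in raw:
        d = dict(raw["design"])
        if "conditions" in d:
            d["conditions"] = tuple(d["conditions"])
        d["geometry"] = kwargs.get("geometry", TaskGeometry())
        kwargs["design"] = _build(DesignSpec, d, "design")
    if "population" in raw:
        p = dict(raw["population"])
        if "order_weights" in p:
            p["order_weights"] = tuple(p["order_weights"])
        defaults = asdict(ModelParams.default())
        defaults.update(p)
        kwargs["population"] = _build(ModelParams, defaults, "population")
    if "prior" in raw:
        p = dict(raw["prior"])
        if "order_concentration" in p:
            p["order_concentration"] = tuple(p["order_concentration"])
        kwargs["prior"] = _build(PopulationPrior, p, "prior")
    if "mcmc" in raw:
        kwargs["mcmc"] = _build(McmcConfig, raw["mcmc"], "mcmc")
    for key in ("population_sd", "variant", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    return RunConfig(**kwargs)
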