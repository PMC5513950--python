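"""Pipeline configuration: one object bundling every stage's settings.

Serialisable to/from YAML so that a run is fully described by
(input data, config, seed); the CLI echoes the effective config and seed to
standard error and into the run-metadata file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .errors import ConfigurationError
from .fit import OptimizerConfig
from .mcmc import MCMCConfig
from .priors import PriorFactors
from .report import DEFAULT_BAND_SAMPLES, DEFAULT_TIMEPOINTS

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable settings of the fit/sample/report pipeline."""

    mcmc: MCMCConfig = MCMCConfig()
    optimizer: OptimizerConfig = OptimizerConfig()
    prior_factors: PriorFactors = PriorFactors()
    band_samples: int = DEFAULT_BAND_SAMPLES
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    level: float = 0.95
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.band_samples < 1:
            raise ConfigurationError("band_samples must be >= 1")
        if self.band_samples > self.mcmc.chains * self.mcmc.retained_per_chain:
            raise ConfigurationError(
                f"band_samples={self.band_samples} exceeds the "
                f"{self.mcmc.chains * self.mcmc.retained_per_chain} retained draws"
            )
        if not (0.0 < self.level < 1.0):
            raise ConfigurationError("level must be in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kwargs: dict = {}
        if "mcmc" in d:
            kwargs["mcmc"] = MCMCConfig(**d.pop("mcmc"))
        if "optimizer" in d:
            opt = d.pop("optimizer")
            if "mutation" in opt:
                opt["mutation"] = tuple(opt["mutation"])
            kwargs["optimizer"] = OptimizerConfig(**opt)
        if "prior_factors" in d:
            kwargs["prior_factors"] = PriorFactors(**d.pop("prior_factors"))
        if "timepoints" in d:
            kwargs["timepoints"] = tuple(float(t) for t in d.pop("timepoints"))
        for key in ("band_samples", "level", "seed"):
            if key in d:
                kwargs[key] = d.pop(key)
        if d:
            raise ConfigurationError(f"unknown config keys: {sorted(d)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
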