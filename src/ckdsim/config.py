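"""Run configuration: YAML/JSON loading with defaults and validation.

A run is fully described by one mapping with optional blocks
``population``, ``transitions``, ``utilities``, ``costs``, ``strategy``
plus scalar keys ``start_year``, ``horizon``, ``replicates``,
``master_seed``, ``output_dir``. Anything omitted takes the documented
default; unknown keys are rejected with their field path.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .burden_accounting import CostParams, UtilityParams
from .errors import ConfigurationError, ParameterError
from .screening_strategies import Strategy, get_strategy
from .synthetic_population import PopulationSpec
from .transition_model import TransitionParameters

__all__ = ["RunConfig", "load_config", "strategy_from_config"]

_SCALAR_DEFAULTS = {
    "start_year": 2024,
    "horizon": 10,
    "replicates": 1,
    "master_seed": 12345,
    "output_dir": "out",
    "discount_qalys": False,
    "microdata": None,
}


def strategy_from_config(block: dict) -> Strategy:
    """Build a Strategy from a config block.

    ``name`` selects a built-in (or ``custom`` with an explicit
    ``criteria`` list); ``schedule``, unit costs and ``participation``
    override the defaults.
    """
    block = dict(block)
    name = block.pop("name", "hypertension_diabetes_age65")
    overrides = {}
    for key in ("schedule", "cost_urinalysis", "cost_creatinine", "participation"):
        if key in block:
            overrides[key] = block.pop(key)
    criteria = block.pop("criteria", None)
    if block:
        raise ConfigurationError(f"strategy: unknown keys {sorted(block)}")
    if name == "custom":
        if not criteria:
            raise ConfigurationError("strategy: 'custom' requires a criteria list")
        return Strategy("custom", frozenset(criteria), **overrides)
    if criteria is not None:
        raise ConfigurationError(
            "strategy: criteria may only be given with name 'custom'"
        )
    return get_strategy(name, **overrides)


@dataclass
class RunConfig:
    """Validated configuration for one simulation run."""

    population: PopulationSpec = field(default_factory=PopulationSpec)
    transitions: TransitionParameters = field(default_factory=TransitionParameters)
    utilities: UtilityParams = field(default_factory=UtilityParams)
    costs: CostParams = field(default_factory=CostParams)
    strategy: Strategy = field(
        default_factory=lambda: get_strategy("hypertension_diabetes_age65")
    )
    start_year: int = _SCALAR_DEFAULTS["start_year"]
    horizon: int = _SCALAR_DEFAULTS["horizon"]
    replicates: int = _SCALAR_DEFAULTS["replicates"]
    master_seed: int = _SCALAR_DEFAULTS["master_seed"]
    output_dir: str = _SCALAR_DEFAULTS["output_dir"]
    discount_qalys: bool = False
    microdata: Optional[str] = None  # path to a cohort CSV; synthesized if absent

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ParameterError(f"horizon must be >= 1, got {self.horizon}")
        if self.replicates < 1:
            raise ParameterError(f"replicates must be >= 1, got {self.replicates}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d or {})
        kwargs = {}
        try:
            if "population" in d:
                kwargs["population"] = PopulationSpec.from_dict(d.pop("population"))
            if "transitions" in d:
                kwargs["transitions"] = TransitionParameters.from_dict(
                    d.pop("transitions")
                )
            if "utilities" in d:
                kwargs["utilities"] = UtilityParams.from_dict(d.pop("utilities"))
            if "costs" in d:
                kwargs["costs"] = CostParams.from_dict(d.pop("costs"))
            if "strategy" in d:
                kwargs["strategy"] = strategy_from_config(d.pop("strategy"))
        except TypeError as exc:  # unexpected field inside a block
            raise ConfigurationError(str(exc)) from None
        for key in _SCALAR_DEFAULTS:
            if key in d:
                kwargs[key] = d.pop(key)
        if d:
            raise ConfigurationError(f"unknown config keys: {sorted(d)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "population": self.population.to_dict(),
            "transitions": self.transitions.to_dict(),
            "utilities": self.utilities.to_dict(),
            "costs": self.costs.to_dict(),
            "strategy": {
                "name": self.strategy.name,
                **(
                    {"criteria": sorted(self.strategy.criteria)}
                    if self.strategy.name == "custom"
                    else {}
                ),
                "schedule": self.strategy.schedule,
                "cost_urinalysis": self.strategy.cost_urinalysis,
                "cost_creatinine": self.strategy.cost_creatinine,
                "participation": self.strategy.participation,
            },
            "start_year": self.start_year,
            "horizon": self.horizon,
            "replicates": self.replicates,
            "master_seed": self.master_seed,
            "output_dir": self.output_dir,
            "discount_qalys": self.discount_qalys,
            "microdata": self.microdata,
        }

    def digest(self) -> str:
        """Stable hash of the fully-defaulted configuration (audit log)."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path: Optional[str | Path]) -> RunConfig:
    """Load a YAML (or JSON — YAML is a superset) config file; ``None``
    yields the all-defaults configuration."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    return RunConfig.from_dict(data)
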