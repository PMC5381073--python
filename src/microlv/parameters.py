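"""Model parameters and population state for the serial-dilution predator-prey map.

The model tracks a density-limited prey population P (cells/ml) and a
predator C (cells/ml) that grows exponentially on an alternative resource
and on prey. Rates are expressed per iteration step (7.5 min by default,
192 steps per 24 h day).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

#: Calibrated reference parameter values for the study system
#: (E. coli prey, Tetrahymena predator, daily tenfold serial dilution).
REFERENCE_PARAMS = {
    "r_P": 0.094,
    "r_C": 0.012,
    "K_P": 4.9e8,
    "c_P": 3.5e-6,
    "c_C": 1.4e-11,
    "step_minutes": 7.5,
    "steps_per_day": 192,
}

_PARAM_FIELDS = ("r_P", "r_C", "K_P", "c_P", "c_C", "step_minutes", "steps_per_day")


@dataclass(frozen=True)
class ModelParameters:
    """Parameters of the discrete-time predator-prey map.

    Attributes
    ----------
    r_P : float
        Prey growth rate per step (dimensionless per 7.5-min step).
    r_C : float
        Predator growth rate per step in the absence of prey; encodes the
        predator's coupling to an alternative (dissolved) resource.
        ``r_C = 0`` removes that coupling.
    K_P : float
        Prey carrying capacity (cells/ml).
    c_P : float
        Prey interaction coefficient: per-predator prey loss (ml/cell/step).
    c_C : float
        Predator interaction coefficient: conversion of consumed prey into
        predator growth (ml/cell/step).
    step_minutes : float
        Duration of one iteration step in minutes.
    steps_per_day : int
        Iterations per 24 h; must satisfy steps_per_day * step_minutes == 1440.
    """

    r_P: float = REFERENCE_PARAMS["r_P"]
    r_C: float = REFERENCE_PARAMS["r_C"]
    K_P: float = REFERENCE_PARAMS["K_P"]
    c_P: float = REFERENCE_PARAMS["c_P"]
    c_C: float = REFERENCE_PARAMS["c_C"]
    step_minutes: float = REFERENCE_PARAMS["step_minutes"]
    steps_per_day: int = REFERENCE_PARAMS["steps_per_day"]

    def __post_init__(self) -> None:
        if self.r_P < 0:
            raise ValueError(f"r_P must be >= 0, got {self.r_P}")
        if not self.K_P > 0:
            raise ValueError(f"K_P must be > 0, got {self.K_P}")
        if self.r_C < 0:
            raise ValueError(f"r_C must be >= 0, got {self.r_C}")
        if self.c_P < 0 or self.c_C < 0:
            raise ValueError("interaction coefficients must be >= 0")
        if abs(self.steps_per_day * self.step_minutes - 1440.0) > 1e-9:
            raise ValueError(
                "steps_per_day * step_minutes must equal 1440 minutes, got "
                f"{self.steps_per_day} * {self.step_minutes}"
            )

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in _PARAM_FIELDS}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        unknown = set(d) - set(_PARAM_FIELDS)
        if unknown:
            raise ValueError(f"unknown parameter fields: {sorted(unknown)}")
        kwargs = dict(d)
        if "steps_per_day" in kwargs:
            kwargs["steps_per_day"] = int(kwargs["steps_per_day"])
        return cls(**kwargs)


@dataclass(frozen=True)
class PopulationState:
    """Instantaneous abundances (cells/ml) at step index ``t``."""

    P: float
    C: float
    t: int = 0

    def __post_init__(self) -> None:
        if self.P < 0 or self.C < 0:
            raise ValueError(f"abundances must be >= 0, got P={self.P}, C={self.C}")


def write_params(params: ModelParameters, path: str | Path) -> None:
    """Write a parameter set as a flat key-value config file."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def read_params(path: str | Path) -> ModelParameters:
    """Read a parameter set from a flat key-value config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat key-value mapping")
    return ModelParameters.from_dict(data)
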