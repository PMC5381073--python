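"""Containers and delimited-text I/O for observed count data.

Two shapes of data are handled: daily microcosm counts with replicates
(``day,replicate,prey,predator``) and hourly growth-curve samples per
culture setup (``setup,replicate,hour,prey,predator``; empty cells for
species absent from a setup).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GROWTH_SETUPS = ("prey_only", "predator_axenic", "co_culture")


@dataclass
class ObservedSeries:
    """Replicated daily counts of prey and predator (cells/ml).

    Wraps a tidy frame with columns ``day, replicate, prey, predator``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"day", "replicate", "prey", "predator"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"observed series missing columns: {sorted(missing)}")
        if len(self.data) == 0:
            raise ValueError("observed series is empty")
        if (self.data[["prey", "predator"]] < 0).any().any():
            raise ValueError("abundances must be >= 0")
        self.data = self.data.sort_values(["day", "replicate"]).reset_index(drop=True)

    @property
    def days(self) -> np.ndarray:
        return np.unique(self.data["day"].to_numpy())

    @property
    def n_replicates(self) -> int:
        return self.data["replicate"].nunique()

    def replicate_means(self) -> pd.DataFrame:
        """Per-day replicate mean, indexed by day."""
        return self.data.groupby("day")[["prey", "predator"]].mean()

    def replicate_sds(self) -> pd.DataFrame:
        return self.data.groupby("day")[["prey", "predator"]].std(ddof=1)

    def mean_series(self, species: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.replicate_means()
        return m.index.to_numpy(), m[species].to_numpy()

    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ObservedSeries":
        return cls(pd.read_csv(path, float_precision="round_trip"))


@dataclass
class GrowthCurveData:
    """Hourly counts from one 24 h growth-curve setup (no dilution).

    ``samples`` has columns ``replicate, hour, prey, predator`` with NaN
    for the species absent from the setup. Default initial abundances
    follow the growth-curve experimental design (prey 4e6 cells/ml,
    predator 2500 cells/ml).
    """

    setup: str
    samples: pd.DataFrame
    init_P: float = 4e6
    init_C: float = 2500.0

    def __post_init__(self) -> None:
        if self.setup not in GROWTH_SETUPS:
            raise ValueError(f"setup must be one of {GROWTH_SETUPS}, got {self.setup!r}")
        required = {"replicate", "hour", "prey", "predator"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"growth curve missing columns: {sorted(missing)}")
        hours = self.samples["hour"].to_numpy()
        if np.any(hours < 0) or np.any(hours > 24):
            raise ValueError("growth-curve hours must lie in [0, 24]")
        self.samples = self.samples.sort_values(["replicate", "hour"]).reset_index(drop=True)
        # the absent species starts (and stays) at zero in single-species setups
        if self.setup == "prey_only":
            object.__setattr__(self, "init_C", 0.0)
        elif self.setup == "predator_axenic":
            object.__setattr__(self, "init_P", 0.0)

    @property
    def hours(self) -> np.ndarray:
        return np.unique(self.samples["hour"].to_numpy())

    def species_observed(self) -> list[str]:
        out = []
        for sp in ("prey", "predator"):
            if self.samples[sp].notna().any():
                out.append(sp)
        return out


def write_growth_curves(curves: dict[str, GrowthCurveData], path: str | Path) -> None:
    """Write all setups to one ``setup,replicate,hour,prey,predator`` file."""
    frames = []
    for setup in GROWTH_SETUPS:
        if setup in curves:
            df = curves[setup].samples.copy()
            df.insert(0, "setup", setup)
            frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_growth_curves(
    path: str | Path, inits: dict[str, tuple[float, float]] | None = None
) -> dict[str, GrowthCurveData]:
    """Read growth curves; ``inits`` maps setup -> (init_P, init_C)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "setup" not in df.columns:
        raise ValueError(f"{path}: missing 'setup' column")
    curves: dict[str, GrowthCurveData] = {}
    for setup, grp in df.groupby("setup"):
        if setup not in GROWTH_SETUPS:
            raise ValueError(f"{path}: unknown setup {setup!r}")
        kwargs = {}
        if inits and setup in inits:
            kwargs = {"init_P": inits[setup][0], "init_C": inits[setup][1]}
        curves[setup] = GrowthCurveData(
            setup=setup, samples=grp.drop(columns="setup"), **kwargs
        )
    return curves
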