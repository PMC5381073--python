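"""Dilution schedules encoding control, press, and pulse disturbance regimes.

A fold-f transfer retains fraction 1/f of the culture, equivalent to a
per-day mortality rate d = 1 - 1/f. A press disturbance is a sustained
window of elevated daily dilution (default 40-fold for 10 days); a pulse
is a single severe event (default 2500-fold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

REGIME_KINDS = ("control", "press", "pulse")


def fold_to_rate(fold: float) -> float:
    """Per-day dilution rate d = 1 - 1/fold for a fold >= 1 transfer."""
    if fold < 1:
        raise ValueError(f"dilution fold must be >= 1, got {fold}")
    return 1.0 - 1.0 / fold


def rate_to_fold(rate: float) -> float:
    """Inverse of :func:`fold_to_rate`: fold = 1 / (1 - rate)."""
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"dilution rate must be in [0, 1), got {rate}")
    return 1.0 / (1.0 - rate)


@dataclass(frozen=True)
class DisturbanceRegime:
    """A disturbance regime on top of a constant baseline serial dilution.

    ``start_day`` is 1-based: the dilution event at the start of day
    ``start_day`` is the first disturbed one. A pulse always has
    ``duration_days = 1``.
    """

    kind: str = "control"
    baseline_fold: float = 10.0
    disturbance_fold: float = 10.0
    start_day: int = 0
    duration_days: int = 1

    def __post_init__(self) -> None:
        if self.kind not in REGIME_KINDS:
            raise ValueError(f"kind must be one of {REGIME_KINDS}, got {self.kind!r}")
        if self.baseline_fold < 1 or self.disturbance_fold < 1:
            raise ValueError("dilution folds must be >= 1")
        if self.duration_days < 1:
            raise ValueError("duration_days must be >= 1")
        if self.kind == "pulse" and self.duration_days != 1:
            raise ValueError("a pulse disturbance lasts exactly 1 day")

    @property
    def end_day(self) -> int:
        """First day after the disturbance window (baseline resumes here)."""
        return self.start_day + self.duration_days

    def replace(self, **changes) -> "DisturbanceRegime":
        import dataclasses

        return dataclasses.replace(self, **changes)


def control_regime(baseline_fold: float = 10.0) -> DisturbanceRegime:
    return DisturbanceRegime(kind="control", baseline_fold=baseline_fold)


def press_regime(
    disturbance_fold: float = 40.0,
    start_day: int = 22,
    duration_days: int = 10,
    baseline_fold: float = 10.0,
) -> DisturbanceRegime:
    """40-fold daily dilution over days 22..31, baseline resuming on day 32."""
    return DisturbanceRegime(
        kind="press",
        baseline_fold=baseline_fold,
        disturbance_fold=disturbance_fold,
        start_day=start_day,
        duration_days=duration_days,
    )


def pulse_regime(
    disturbance_fold: float = 2500.0,
    start_day: int = 15,
    baseline_fold: float = 10.0,
) -> DisturbanceRegime:
    """A single 2500-fold dilution event on day 15."""
    return DisturbanceRegime(
        kind="pulse",
        baseline_fold=baseline_fold,
        disturbance_fold=disturbance_fold,
        start_day=start_day,
        duration_days=1,
    )


def fold_ratio(regime: DisturbanceRegime) -> float:
    """Disturbance-to-baseline fold ratio (e.g. 40/10 = 4 for the press)."""
    return regime.disturbance_fold / regime.baseline_fold


@dataclass(frozen=True)
class DilutionSchedule:
    """Per-day dilution folds/rates; entry i applies to day i+1's event."""

    folds: np.ndarray
    rates: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        folds = np.asarray(self.folds, dtype=float)
        object.__setattr__(self, "folds", folds)
        if np.any(folds < 1):
            raise ValueError("all folds must be >= 1")
        rates = 1.0 - 1.0 / folds
        if self.rates is not None:
            given = np.asarray(self.rates, dtype=float)
            if not np.allclose(given, rates, rtol=0, atol=1e-12):
                raise ValueError("rates inconsistent with folds (rate = 1 - 1/fold)")
        object.__setattr__(self, "rates", rates)

    @property
    def n_days(self) -> int:
        return len(self.folds)

    def fold_for_day(self, day: int) -> float:
        """Fold of the dilution event at the start of 1-based ``day``."""
        if not 1 <= day <= self.n_days:
            raise ValueError(f"day {day} outside schedule of {self.n_days} days")
        return float(self.folds[day - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": np.arange(1, self.n_days + 1), "fold": self.folds, "rate": self.rates}
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def build_schedule(regime: DisturbanceRegime, n_days: int) -> DilutionSchedule:
    """Expand a regime into one dilution fold per simulated day.

    Days ``start_day .. start_day + duration_days - 1`` carry the
    disturbance fold; every other day carries the baseline fold.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    folds = np.full(n_days, float(regime.baseline_fold))
    if regime.kind != "control":
        first, last = regime.start_day, regime.start_day + regime.duration_days - 1
        if first < 1 or last > n_days:
            raise ValueError(
                f"disturbance window days {first}..{last} outside 1..{n_days}"
            )
        folds[first - 1 : last] = float(regime.disturbance_fold)
    return DilutionSchedule(folds=folds)
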