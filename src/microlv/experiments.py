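"""Scenario runs and simulation sweeps (disturbance duration, strength, r_C).

``run_scenario`` reproduces one experimental protocol (control, press, or
pulse) from its inoculation state and evaluates the transient metrics.
``sweep`` varies one factor -- press duration, pulse fold, or the
alternative-resource coupling r_C -- and measures recovery times. Sweep
runs first equilibrate the community under the baseline regime (the
experiments disturbed communities that had reached equilibrium), then
apply the disturbance; recovery uses the crossing criterion with a small
relative band tolerance, since a fully equilibrated pre-disturbance band
has near-zero width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .disturbance import (
    DisturbanceRegime,
    build_schedule,
    control_regime,
    press_regime,
    pulse_regime,
)
from .dynamics import Trajectory, simulate
from .metrics import (
    EquilibriumBand,
    RecoveryResult,
    TransientMetrics,
    covariance_windows,
    equilibrium_band,
    recovery_time,
    response_time,
)
from .parameters import ModelParameters, PopulationState

#: inoculation densities (cells/ml) of the control and press microcosms
INIT_CONTROL = PopulationState(P=3.6e7, C=4.2e4)
#: the pulse experiment started from lower densities at a similar ratio
INIT_PULSE = PopulationState(P=4e6, C=4e3)

EXTINCTION_FLOOR = 1.0  # cells/ml; deterministic runs cannot hit exact zero


@dataclass
class ScenarioResult:
    trajectory: Trajectory
    metrics: dict[str, TransientMetrics]
    regime: DisturbanceRegime
    params: ModelParameters
    cov_before: float | None = None
    cov_during_after: float | None = None

    def to_dict(self) -> dict:
        return {
            "regime": self.regime.kind,
            "cov_before": self.cov_before,
            "cov_during_after": self.cov_during_after,
            "species": {sp: m.to_dict() for sp, m in self.metrics.items()},
        }


def run_scenario(
    params: ModelParameters,
    regime: DisturbanceRegime,
    init: PopulationState,
    n_days: int,
    band_from_day: int = 7,
    recovery_mode: str = "reach",
    recovery_rel_tol: float = 0.0,
    cov_scaling: str = "max",
    dilution_mode: str = "transfer",
    extinction_floor: float = EXTINCTION_FLOOR,
) -> ScenarioResult:
    """Simulate one treatment and compute its transient metrics.

    The equilibrium band spans day ``band_from_day`` to the disturbance
    start (exclusive); for a control run it spans to the series end and
    response/recovery are undefined.
    """
    schedule = build_schedule(regime, n_days)
    traj = simulate(params, schedule, init, n_days, dilution_mode=dilution_mode)
    disturbed = regime.kind != "control"
    band_to = regime.start_day if disturbed else n_days + 1
    metrics: dict[str, TransientMetrics] = {}
    bands: dict[str, EquilibriumBand] = {}
    for sp in ("prey", "predator"):
        values = traj.species(sp)
        band = equilibrium_band(traj.day, values, band_from_day, band_to, sp)
        bands[sp] = band
        resp: int | None = None
        rec: RecoveryResult | None = None
        if disturbed:
            resp = response_time(traj.day, values, band, regime.start_day)
            rec = recovery_time(
                traj.day, values, band, regime.end_day,
                mode=recovery_mode, rel_tol=recovery_rel_tol,
            )
        extinct = bool(np.any(values[1:] < extinction_floor))
        metrics[sp] = TransientMetrics(
            species=sp, band=band, response=resp, recovery=rec, extinct_flag=extinct
        )
    cov_before = cov_during = None
    if disturbed:
        cov_before, cov_during = covariance_windows(
            traj.day, traj.prey, traj.predator, bands,
            regime.start_day, band_from_day, cov_scaling,
        )
        for sp in metrics:
            metrics[sp].cov_before = cov_before
            metrics[sp].cov_during_after = cov_during
    return ScenarioResult(
        trajectory=traj, metrics=metrics, regime=regime, params=params,
        cov_before=cov_before, cov_during_after=cov_during,
    )


def equilibrate(
    params: ModelParameters,
    baseline_fold: float = 10.0,
    burn_days: int = 150,
    init: PopulationState = INIT_CONTROL,
    dilution_mode: str = "transfer",
) -> PopulationState:
    """Run the baseline regime until the daily cycle settles; return the
    final pre-dilution state."""
    schedule = build_schedule(control_regime(baseline_fold), burn_days)
    traj = simulate(params, schedule, init, burn_days, dilution_mode=dilution_mode)
    return PopulationState(P=float(traj.prey[-1]), C=float(traj.predator[-1]))


@dataclass
class SweepSpec:
    """One-factor sweep specification.

    ``variable`` is one of ``press_duration`` (days of elevated dilution),
    ``pulse_fold`` (strength of the single event), or ``r_C`` (predator
    coupling to the alternative resource). ``post_days`` is the scan
    horizon after the disturbance ends.
    """

    variable: str
    values: tuple
    base_params: ModelParameters = field(default_factory=ModelParameters)
    base_regime: DisturbanceRegime = field(
        default_factory=lambda: pulse_regime(start_day=22)
    )
    init: PopulationState = INIT_CONTROL
    post_days: int = 60
    burn_days: int = 150
    band_from_day: int = 7
    recovery_rel_tol: float = 0.02
    dilution_mode: str = "transfer"

    def __post_init__(self) -> None:
        if self.variable not in ("press_duration", "pulse_fold", "r_C"):
            raise ValueError(f"unknown sweep variable {self.variable!r}")
        vals = np.asarray(self.values, dtype=float)
        if vals.size == 0:
            raise ValueError("sweep values must be non-empty")
        if np.any(np.diff(vals) <= 0):
            raise ValueError("sweep values must be strictly increasing")
        if self.variable == "press_duration" and np.any(vals < 1):
            raise ValueError("press durations must be >= 1 day")
        if self.variable == "pulse_fold" and np.any(vals < 1):
            raise ValueError("pulse folds must be >= 1")
        if self.variable == "r_C" and np.any(vals < 0):
            raise ValueError("r_C values must be >= 0")


@dataclass
class SweepResult:
    spec: SweepSpec
    records: pd.DataFrame  # value, species, recovery_days, censored, extinct
    trajectories: dict[float, Trajectory]

    def recovery_series(self, species: str = "predator") -> pd.DataFrame:
        out = self.records[self.records["species"] == species]
        return out.sort_values("value").reset_index(drop=True)

    def write_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def sweep(spec: SweepSpec) -> SweepResult:
    """Run the sweep: per value, equilibrate, disturb, measure recovery.

    Recovery is measured per species with the crossing criterion against
    that run's own pre-disturbance band (equilibria differ across r_C
    values). Runs whose populations dip below the extinction floor are
    flagged, not errored.
    """
    rows = []
    trajectories: dict[float, Trajectory] = {}
    eq_cache: dict[tuple, PopulationState] = {}
    for value in spec.values:
        params = spec.base_params
        regime = spec.base_regime
        if spec.variable == "press_duration":
            regime = press_regime(
                disturbance_fold=regime.disturbance_fold
                if regime.kind == "press"
                else 40.0,
                start_day=regime.start_day,
                duration_days=int(value),
                baseline_fold=regime.baseline_fold,
            )
        elif spec.variable == "pulse_fold":
            regime = regime.replace(disturbance_fold=float(value))
        else:  # r_C
            params = params.replace(r_C=float(value))
        key = (params.r_P, params.r_C, params.K_P, params.c_P, params.c_C,
               regime.baseline_fold)
        if key not in eq_cache:
            eq_cache[key] = equilibrate(
                params, regime.baseline_fold, spec.burn_days, spec.init,
                spec.dilution_mode,
            )
        n_days = regime.end_day - 1 + spec.post_days
        result = run_scenario(
            params, regime, eq_cache[key], n_days,
            band_from_day=spec.band_from_day,
            recovery_mode="reach",
            recovery_rel_tol=spec.recovery_rel_tol,
            dilution_mode=spec.dilution_mode,
        )
        trajectories[float(value)] = result.trajectory
        for sp in ("predator", "prey"):
            m = result.metrics[sp]
            rows.append(
                {
                    "value": float(value),
                    "species": sp,
                    "recovery_days": m.recovery.days,
                    "censored": m.recovery.censored,
                    "extinct": m.extinct_flag,
                }
            )
    return SweepResult(spec=spec, records=pd.DataFrame(rows), trajectories=trajectories)


# ---------------------------------------------------------------------------
# presets encoding the study's scenarios and sweeps

def control_scenario(n_days: int = 40) -> tuple[ModelParameters, DisturbanceRegime, PopulationState, int]:
    return ModelParameters(), control_regime(), INIT_CONTROL, n_days


def press_scenario(n_days: int = 62) -> tuple[ModelParameters, DisturbanceRegime, PopulationState, int]:
    return ModelParameters(), press_regime(), INIT_CONTROL, n_days


def pulse_scenario(n_days: int = 45) -> tuple[ModelParameters, DisturbanceRegime, PopulationState, int]:
    return ModelParameters(), pulse_regime(), INIT_PULSE, n_days


def press_duration_sweep(values: tuple = tuple(range(2, 13))) -> SweepSpec:
    """Press duration varied 2..12 days at constant 40-fold strength."""
    return SweepSpec(
        variable="press_duration",
        values=tuple(values),
        base_regime=press_regime(start_day=22),
    )


def pulse_fold_sweep(values: tuple = (10.0, 1e2, 1e3, 1e4, 1e5, 1e6)) -> SweepSpec:
    """Pulse strength varied 10..1e6 on a decade grid."""
    return SweepSpec(
        variable="pulse_fold",
        values=tuple(values),
        base_regime=pulse_regime(start_day=22),
    )


def r_c_sweep(values: tuple = (0.007, 0.008, 0.009, 0.010, 0.011)) -> SweepSpec:
    """Alternative-resource coupling varied under a 2500-fold pulse.

    Weak coupling slows predator recovery dramatically, so this sweep uses
    a longer post-disturbance horizon.
    """
    return SweepSpec(
        variable="r_C",
        values=tuple(values),
        base_regime=pulse_regime(disturbance_fold=2500.0, start_day=22),
        post_days=120,
    )
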