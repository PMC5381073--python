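"""Transient-dynamics evaluation metrics.

Implements the quantities used to compare simulated and observed microcosm
dynamics: Nash-Sutcliffe efficiency, the pre-disturbance equilibrium band,
response and recovery times, deviation time (model minus data), and the
windowed prey-predator covariance used to diagnose prey release.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .observations import ObservedSeries


def nash_sutcliffe(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Nash-Sutcliffe efficiency E = 1 - SSE / SST.

    E = 1 for a perfect fit, E = 0 for a model no better than the observed
    mean, and E < 0 when the observed mean would be the better predictor.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError(f"series shapes differ: {pred.shape} vs {obs.shape}")
    if pred.size < 2:
        raise ValueError("need at least 2 points")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("observed series has zero variance; E is undefined")
    sse = float(np.sum((obs - pred) ** 2))
    return 1.0 - sse / sst


@dataclass(frozen=True)
class EquilibriumBand:
    """Min-max envelope of daily abundances over a pre-disturbance window.

    The window is ``[from_day, to_day)`` in sample days; the experimental
    convention starts it at day 7 and ends at the disturbance start.
    """

    low: float
    high: float
    from_day: int
    to_day: int
    species: str = ""

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError("band low must be <= high")

    def contains(self, value: float, rel_tol: float = 0.0) -> bool:
        return self.low * (1 - rel_tol) <= value <= self.high * (1 + rel_tol)


def equilibrium_band(
    days: np.ndarray,
    values: np.ndarray,
    from_day: int,
    to_day: int,
    species: str = "",
) -> EquilibriumBand:
    """Band over sample days ``from_day .. to_day - 1`` (min/max of values)."""
    if from_day >= to_day:
        raise ValueError("from_day must be < to_day")
    days = np.asarray(days)
    values = np.asarray(values, dtype=float)
    mask = (days >= from_day) & (days < to_day)
    if not mask.any():
        raise ValueError(f"no samples in window [{from_day}, {to_day})")
    window = values[mask]
    return EquilibriumBand(
        low=float(window.min()), high=float(window.max()),
        from_day=from_day, to_day=to_day, species=species,
    )


def response_time(
    days: np.ndarray,
    values: np.ndarray,
    band: EquilibriumBand,
    disturbance_start: int,
) -> int | None:
    """Days from disturbance start to the first sample outside the band.

    Returns None when the series never leaves the band over the available
    days (no detectable response).
    """
    if band.to_day > disturbance_start:
        raise ValueError(
            "equilibrium-band window overlaps the post-disturbance scan"
        )
    days = np.asarray(days)
    values = np.asarray(values, dtype=float)
    mask = days >= disturbance_start
    if not mask.any():
        raise ValueError("series does not cover the disturbance start")
    for d, v in zip(days[mask], values[mask]):
        if not band.contains(v):
            return int(d - disturbance_start)
    return None


@dataclass(frozen=True)
class RecoveryResult:
    """Recovery time in days; ``censored`` means no return before series end,
    in which case ``days`` is the scan horizon actually observed."""

    days: int
    censored: bool
    horizon: int

    def __int__(self) -> int:
        return self.days


def recovery_time(
    days: np.ndarray,
    values: np.ndarray,
    band: EquilibriumBand,
    disturbance_end: int,
    mode: str = "band",
    rel_tol: float = 0.0,
) -> RecoveryResult:
    """Days from the end of disturbance to the return to pre-disturbance size.

    ``mode="band"``: first sample day on/after ``disturbance_end`` lying
    inside ``[low, high]`` (optionally widened by ``rel_tol``).

    ``mode="reach"``: first day the population crosses back to the band edge
    from its deficit side -- a population below the band recovers when it
    first reaches ``low * (1 - rel_tol)``, one above when it first drops to
    ``high * (1 + rel_tol)``. This crossing reading is robust to a fast-
    regrowing population stepping over a narrow band between daily samples.

    Never extrapolates: if the series ends before return, the result is
    flagged censored with the observed horizon.
    """
    if mode not in ("band", "reach"):
        raise ValueError(f"mode must be 'band' or 'reach', got {mode!r}")
    days = np.asarray(days)
    values = np.asarray(values, dtype=float)
    mask = days >= disturbance_end
    if not mask.any():
        raise ValueError("series does not cover the disturbance end")
    scan_days = days[mask]
    scan_vals = values[mask]
    horizon = int(scan_days[-1] - disturbance_end)
    lo = band.low * (1 - rel_tol)
    hi = band.high * (1 + rel_tol)
    if mode == "band":
        for d, v in zip(scan_days, scan_vals):
            if lo <= v <= hi:
                return RecoveryResult(int(d - disturbance_end), False, horizon)
        return RecoveryResult(horizon, True, horizon)
    # reach: determine deficit side at the end of disturbance
    v0 = scan_vals[0]
    if lo <= v0 <= hi:
        return RecoveryResult(0, False, horizon)
    below = v0 < lo
    for d, v in zip(scan_days, scan_vals):
        if (below and v >= lo) or (not below and v <= hi):
            return RecoveryResult(int(d - disturbance_end), False, horizon)
    return RecoveryResult(horizon, True, horizon)


def deviation_time(
    model_days: np.ndarray,
    model_values: np.ndarray,
    observed: ObservedSeries,
    species: str,
    from_day: int,
    to_day: int,
    event_day: int,
    which: str = "response",
    recovery_mode: str = "band",
    rel_tol: float = 0.0,
) -> float | None:
    """Deviation time D_T: model response (or recovery) time minus the
    response (or recovery) time of the replicate-mean observed series.

    Negative D_T means the model responds (recovers) earlier than the data.
    Each series uses its own equilibrium band over ``[from_day, to_day)``.
    Returns None (undefined) if either response is undefined.
    """
    if which not in ("response", "recovery"):
        raise ValueError("which must be 'response' or 'recovery'")
    obs_days, obs_values = observed.mean_series(species)
    m_band = equilibrium_band(model_days, model_values, from_day, to_day, species)
    o_band = equilibrium_band(obs_days, obs_values, from_day, to_day, species)
    if which == "response":
        t_model = response_time(model_days, model_values, m_band, event_day)
        t_obs = response_time(obs_days, obs_values, o_band, event_day)
        if t_model is None or t_obs is None:
            return None
        return float(t_model - t_obs)
    r_model = recovery_time(model_days, model_values, m_band, event_day, recovery_mode, rel_tol)
    r_obs = recovery_time(obs_days, obs_values, o_band, event_day, recovery_mode, rel_tol)
    if r_model.censored or r_obs.censored:
        return None
    return float(r_model.days - r_obs.days)


def prey_release_covariance(
    days: np.ndarray,
    prey: np.ndarray,
    predator: np.ndarray,
    window: tuple[int, int],
    scaling: str = "max",
) -> float:
    """Sample covariance of the two (rescaled) series over ``[from, to)`` days.

    Each series is first rescaled over the FULL experiment so covariances
    are comparable across treatments: ``scaling="max"`` divides by the
    series maximum, ``"zscore"`` standardizes, ``"log10"`` takes log10 of
    positive counts, ``"none"`` leaves raw cells/ml. A covariance that is
    more negative during/after the disturbance than before it diagnoses
    prey release (prey rising as the predator falls).
    """
    days = np.asarray(days)
    prey = np.asarray(prey, dtype=float)
    predator = np.asarray(predator, dtype=float)
    if scaling == "max":
        p = prey / prey.max() if prey.max() > 0 else prey
        c = predator / predator.max() if predator.max() > 0 else predator
    elif scaling == "zscore":
        p = (prey - prey.mean()) / (prey.std(ddof=1) or 1.0)
        c = (predator - predator.mean()) / (predator.std(ddof=1) or 1.0)
    elif scaling == "log10":
        with np.errstate(divide="ignore"):
            p = np.log10(np.where(prey > 0, prey, np.nan))
            c = np.log10(np.where(predator > 0, predator, np.nan))
    elif scaling == "none":
        p, c = prey, predator
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    from_day, to_day = window
    mask = (days >= from_day) & (days < to_day)
    if mask.sum() < 2:
        raise ValueError(f"covariance window [{from_day}, {to_day}) has < 2 samples")
    pw, cw = p[mask], c[mask]
    if np.ptp(pw) == 0 or np.ptp(cw) == 0:
        return 0.0
    return float(np.cov(pw, cw, ddof=1)[0, 1])


@dataclass
class TransientMetrics:
    """Per-species transient metrics for one scenario run."""

    species: str
    band: EquilibriumBand
    response: int | None
    recovery: RecoveryResult | None
    cov_before: float | None = None
    cov_during_after: float | None = None
    extinct_flag: bool = False
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "band_low": self.band.low,
            "band_high": self.band.high,
            "response_time": self.response,
            "recovery_time": None if self.recovery is None else self.recovery.days,
            "recovery_censored": None if self.recovery is None else self.recovery.censored,
            "cov_before": self.cov_before,
            "cov_during_after": self.cov_during_after,
            "extinct_flag": self.extinct_flag,
            "notes": list(self.notes),
        }


def model_efficiency(
    trajectory_days: np.ndarray,
    trajectory_values: np.ndarray,
    observed: ObservedSeries,
    species: str,
) -> float:
    """Nash-Sutcliffe E of a simulated series against observed replicate means,
    aligned on the days present in both series."""
    obs_days, obs_vals = observed.mean_series(species)
    t_days = np.asarray(trajectory_days)
    common = np.intersect1d(t_days, obs_days)
    if len(common) < 2:
        raise ValueError("fewer than 2 common days between model and data")
    pred = np.asarray(trajectory_values, dtype=float)[np.searchsorted(t_days, common)]
    obs = obs_vals[np.searchsorted(obs_days, common)]
    return nash_sutcliffe(pred, obs)


def covariance_windows(
    days: np.ndarray,
    prey: np.ndarray,
    predator: np.ndarray,
    bands: dict[str, EquilibriumBand],
    disturbance_start: int,
    band_from_day: int = 7,
    scaling: str = "max",
) -> tuple[float, float]:
    """Before vs during/after prey-predator covariance around a disturbance.

    "Before" spans the equilibrium window (band start to disturbance start);
    "during/after" runs from the first disturbed day until the first day
    both species are back inside their bands, or the series end.
    """
    days = np.asarray(days)
    end = int(days[-1]) + 1
    both_in = None
    for d in days[days >= disturbance_start]:
        i = int(np.searchsorted(days, d))
        if bands["prey"].contains(prey[i]) and bands["predator"].contains(predator[i]):
            both_in = int(d) + 1
            break
    during_to = both_in if both_in is not None else end
    if during_to - disturbance_start < 2:
        during_to = min(disturbance_start + 2, end)
    cov_before = prey_release_covariance(
        days, prey, predator, (band_from_day, disturbance_start), scaling
    )
    cov_during = prey_release_covariance(
        days, prey, predator, (disturbance_start, during_to), scaling
    )
    return cov_before, cov_during
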