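"""Thermal-time emergence: air-to-soil regression, degree days, Gompertz curve.

Seedling emergence is driven by soil thermal time (degree days above a base
temperature) accumulated from a fixed start date in early March. Cumulative
percent emergence follows a Gompertz curve of thermal time; the season's
emergence is split into three cohorts (March, April, May--June) by taking the
increments of that curve at three boundary dates.

Soil temperature is predicted from air temperature with a linear regression
(slope 0.84, intercept 3.81 degC); the base temperature for germination is
1.9 degC. The Gompertz curve uses rate k = 0.0151 per degree day and location
444.20 degree days; these constants are inputs, not refit here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import TemperatureSeries

__all__ = [
    "EmergenceModel",
    "ThermalTimeSeries",
    "CohortSchedule",
    "soil_temperature",
    "daily_degree_days",
    "accumulate_thermal_time",
    "gompertz_percent",
    "cohort_fractions",
    "fractions_from_temperatures",
]

MonthDay = tuple[int, int]


def _md(value) -> MonthDay:
    """Coerce 'MM-DD' strings or (month, day) pairs to a validated tuple."""
    if isinstance(value, str):
        month, day = (int(p) for p in value.split("-"))
    else:
        month, day = (int(p) for p in value)
    if not (1 <= month <= 12 and 1 <= day <= 31):
        raise ValueError(f"invalid month-day {value!r}")
    return (month, day)


@dataclass(frozen=True)
class EmergenceModel:
    """Constants of the thermal-time emergence model.

    asymptote: upper limit of cumulative emergence (%).
    gompertz_rate: Gompertz rate k (per degree day).
    gompertz_location: thermal time at which emergence reaches asymptote/e.
    t_base: lowest soil temperature (degC) at which germination proceeds.
    soil_slope / soil_intercept: linear air-to-soil temperature regression.
    count_start: (month, day) at which thermal accumulation starts; this day
        contributes its own degree days (inclusive convention).
    """

    asymptote: float = 100.0
    gompertz_rate: float = 0.0151
    gompertz_location: float = 444.20
    t_base: float = 1.9
    soil_slope: float = 0.84
    soil_intercept: float = 3.81
    count_start: MonthDay = (3, 10)

    def __post_init__(self) -> None:
        object.__setattr__(self, "count_start", _md(self.count_start))
        if self.gompertz_rate <= 0:
            raise ValueError("gompertz_rate must be > 0")
        if self.asymptote != 100.0:
            raise ValueError("asymptote is fixed at 100%")
        # degree days must be attainable for some plausible air temperature
        if self.t_base >= self.soil_intercept + self.soil_slope * 50.0:
            raise ValueError("t_base unattainably high for any plausible temperature")


@dataclass(frozen=True)
class ThermalTimeSeries:
    """Cumulative soil thermal time (degree days) per date from count_start."""

    dates: pd.DatetimeIndex
    cumulative: np.ndarray

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.dates)
        tt = np.asarray(self.cumulative, dtype=float)
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "cumulative", tt)
        if len(dates) != len(tt):
            raise ValueError("dates and cumulative thermal time differ in length")
        if np.any(tt < 0):
            raise ValueError("cumulative thermal time must be non-negative")
        if np.any(np.diff(tt) < 0):
            raise ValueError("cumulative thermal time must be non-decreasing")

    def value_on(self, date) -> float:
        ts = pd.Timestamp(date)
        idx = self.dates.get_indexer([ts])
        if idx[0] < 0:
            raise ValueError(
                f"thermal-time series ({self.dates[0].date()}..{self.dates[-1].date()}) "
                f"does not cover {ts.date()}"
            )
        return float(self.cumulative[idx[0]])


@dataclass(frozen=True)
class CohortSchedule:
    """Three cohort-boundary dates and the fraction-normalization switch.

    Cohort 1 runs from count_start to the first boundary (default March 31),
    cohort 2 to the second (April 30), cohort 3 to the third (June 30; May
    emergence is assigned to cohort 3). With ``normalize_fractions`` on
    (default), the three Gompertz increments are rescaled to sum to one so
    the season's whole emerged pool is allocated; off, the raw increments are
    used and the residual is treated as fatal (non-emerging) germination.
    """

    boundary_dates: tuple[MonthDay, MonthDay, MonthDay] = ((3, 31), (4, 30), (6, 30))
    normalize_fractions: bool = True

    def __post_init__(self) -> None:
        bounds = tuple(_md(b) for b in self.boundary_dates)
        object.__setattr__(self, "boundary_dates", bounds)
        if len(bounds) != 3:
            raise ValueError("exactly three cohort boundaries are required")
        if not bounds[0] < bounds[1] < bounds[2]:
            raise ValueError(f"cohort boundaries must be strictly ordered, got {bounds}")

    def validate_against(self, model: EmergenceModel) -> None:
        if not model.count_start < self.boundary_dates[0]:
            raise ValueError(
                f"count_start {model.count_start} must precede first boundary "
                f"{self.boundary_dates[0]}"
            )


def soil_temperature(air_t, model: EmergenceModel):
    """Predict mean daily soil temperature from air temperature (linear)."""
    return model.soil_slope * np.asarray(air_t, dtype=float) + model.soil_intercept


def daily_degree_days(soil_t, model: EmergenceModel):
    """Degree days contributed by one day: max(0, soil_t - t_base).

    Days colder than the base temperature contribute zero (clipped) so
    cumulative thermal time never decreases.
    """
    return np.maximum(0.0, np.asarray(soil_t, dtype=float) - model.t_base)


def accumulate_thermal_time(
    series: TemperatureSeries, model: EmergenceModel
) -> ThermalTimeSeries:
    """Cumulative degree days from count_start (inclusive) to the series end.

    The series must contain the count_start date of some year; accumulation
    runs from the first such date.
    """
    month, day = model.count_start
    starts = (series.dates.month == month) & (series.dates.day == day)
    if not starts.any():
        raise ValueError(
            f"series {series.dates[0].date()}..{series.dates[-1].date()} does not "
            f"cover the accumulation start {month:02d}-{day:02d}"
        )
    i0 = int(np.argmax(starts))
    dd = daily_degree_days(soil_temperature(series.values[i0:], model), model)
    return ThermalTimeSeries(series.dates[i0:], np.cumsum(dd))


def gompertz_percent(tt, model: EmergenceModel):
    """Cumulative percent emergence at thermal time tt (Gompertz curve).

    y(tt) = 100 exp(-exp(-k (tt - location))); bounded in [0, 100] and
    non-decreasing in tt.
    """
    tt = np.asarray(tt, dtype=float)
    if np.any(tt < 0):
        raise ValueError("thermal time must be non-negative")
    return model.asymptote * np.exp(
        -np.exp(-model.gompertz_rate * (tt - model.gompertz_location))
    )


def fractions_from_boundary_tt(
    boundary_tt, model: EmergenceModel, normalize: bool
) -> np.ndarray:
    """Cohort fractions from cumulative thermal time at the three boundaries."""
    y = gompertz_percent(np.asarray(boundary_tt, dtype=float), model) / model.asymptote
    if y[2] <= 0.0:
        raise ValueError("no emergence window: zero cumulative emergence at final boundary")
    raw = np.diff(np.concatenate(([0.0], y)))
    if normalize:
        return raw / raw.sum()
    return raw


def cohort_fractions(
    tt: ThermalTimeSeries, schedule: CohortSchedule, model: EmergenceModel
) -> np.ndarray:
    """Allocate cumulative Gompertz emergence to the three seasonal cohorts.

    Returns the fraction of the season's emerging seedlings assigned to each
    cohort: increments of the cumulative curve at the boundary dates,
    renormalized to sum to one unless ``normalize_fractions`` is off.
    """
    schedule.validate_against(model)
    year = tt.dates[0].year
    boundary_tt = [
        tt.value_on(pd.Timestamp(year=year, month=m, day=d))
        for (m, d) in schedule.boundary_dates
    ]
    return fractions_from_boundary_tt(boundary_tt, model, schedule.normalize_fractions)


def fractions_from_temperatures(
    air_temps: np.ndarray,
    boundary_indices,
    model: EmergenceModel,
    normalize: bool = True,
) -> np.ndarray:
    """Fast path used by the simulation engine.

    ``air_temps`` is the daily air-temperature array starting at count_start;
    ``boundary_indices`` are the 0-based positions of the three boundary
    dates within it.
    """
    dd = daily_degree_days(soil_temperature(air_temps, model), model)
    tt = np.cumsum(dd)
    return fractions_from_boundary_tt(tt[list(boundary_indices)], model, normalize)


def percent_emerged_on(series: TemperatureSeries, date, model: EmergenceModel) -> float:
    """Convenience: cumulative percent emergence on a calendar date."""
    tt = accumulate_thermal_time(series, model)
    return float(gompertz_percent(tt.value_on(date), model))


def gompertz_location_for(percent: float, model: EmergenceModel) -> float:
    """Thermal time at which the curve reaches ``percent`` (inverse Gompertz)."""
    if not 0 < percent < model.asymptote:
        raise ValueError("percent must be strictly between 0 and the asymptote")
    return model.gompertz_location - math.log(-math.log(percent / model.asymptote)) / model.gompertz_rate
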