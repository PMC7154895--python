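"""Daily air-temperature series: synthetic climatology, CSV I/O, warming scenarios.

The emergence model is driven purely by daily mean air temperature. Series can
be read from a two-column CSV (``date,tmean_air_c``) or generated from a smooth
sinusoidal climatology with Gaussian daily noise, emulating a subtropical
Southern-Hemisphere site (warm January, cooling through the March--June
emergence season). A climate scenario is a uniform additive offset in degrees
Celsius applied to the whole series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureSeries",
    "ClimatologyConfig",
    "ScenarioConfig",
    "generate_synthetic_series",
    "expected_temperature",
    "read_temperature_csv",
    "write_temperature_csv",
    "apply_scenario",
]

#: Hard plausibility bounds; values outside are treated as corrupt input.
TEMP_MIN_C = -30.0
TEMP_MAX_C = 50.0

DATE_COLUMN = "date"
TEMP_COLUMN = "tmean_air_c"

#: Mean tropical-year length used for the seasonal phase.
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class TemperatureSeries:
    """Contiguous daily mean air temperatures (degrees C) for one site.

    Dates must be strictly increasing with exactly one record per calendar
    day and no gaps; temperatures must be finite and within plausible bounds.
    """

    dates: pd.DatetimeIndex
    values: np.ndarray
    site_label: str = ""

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.dates)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "values", values)
        if len(dates) != len(values):
            raise ValueError(
                f"dates ({len(dates)}) and values ({len(values)}) differ in length"
            )
        if len(dates) == 0:
            raise ValueError("temperature series is empty")
        deltas = np.diff(dates.values).astype("timedelta64[D]").astype(int)
        if np.any(deltas <= 0):
            i = int(np.argmax(deltas <= 0))
            raise ValueError(
                f"dates not strictly increasing at {dates[i].date()} -> {dates[i + 1].date()}"
            )
        if np.any(deltas != 1):
            i = int(np.argmax(deltas != 1))
            raise ValueError(
                f"gap in daily series between {dates[i].date()} and {dates[i + 1].date()}"
            )
        if not np.all(np.isfinite(values)):
            i = int(np.argmax(~np.isfinite(values)))
            raise ValueError(f"non-finite temperature at {dates[i].date()}")
        if np.any((values < TEMP_MIN_C) | (values > TEMP_MAX_C)):
            i = int(np.argmax((values < TEMP_MIN_C) | (values > TEMP_MAX_C)))
            raise ValueError(
                f"temperature {values[i]:.1f} degC at {dates[i].date()} outside "
                f"plausible range [{TEMP_MIN_C}, {TEMP_MAX_C}]"
            )

    def __len__(self) -> int:
        return len(self.dates)

    def slice(self, start, end) -> "TemperatureSeries":
        """Sub-series covering [start, end] inclusive."""
        mask = (self.dates >= pd.Timestamp(start)) & (self.dates <= pd.Timestamp(end))
        if not mask.any():
            raise ValueError(f"series does not cover {start}..{end}")
        return TemperatureSeries(self.dates[mask], self.values[mask], self.site_label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({DATE_COLUMN: self.dates, TEMP_COLUMN: self.values})


@dataclass(frozen=True)
class ClimatologyConfig:
    """Sinusoidal annual temperature cycle with daily Gaussian noise.

    Defaults emulate a cool subtropical highland site in Southern Brazil:
    annual mean 13.5 degC, half peak-to-trough amplitude 5.5 degC, warmest
    day in mid-January (southern-hemisphere phase, so March--June is the
    cooling season), daily noise sd 2.0 degC. The mean is calibrated so the
    noise-free emergence flow spreads over the three cohort windows (a small
    March flush, the bulk in April, a trace into June) as the three-cohort
    life cycle describes. These are synthetic stand-in values and fully
    configurable; no observed weather record is packaged.
    """

    annual_mean: float = 13.5
    annual_amplitude: float = 5.5
    warmest_day_of_year: int = 15
    daily_noise_sd: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.annual_amplitude < 0:
            raise ValueError("annual_amplitude must be >= 0")
        if self.daily_noise_sd < 0:
            raise ValueError("daily_noise_sd must be >= 0")

    def without_noise(self) -> "ClimatologyConfig":
        return ClimatologyConfig(
            self.annual_mean, self.annual_amplitude, self.warmest_day_of_year, 0.0, self.rng_seed
        )


@dataclass(frozen=True)
class ScenarioConfig:
    """Named additive warming offset (degC); 0.0 is the current climate."""

    name: str = "scenario1"
    delta_T: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta_T):
            raise ValueError("delta_T must be finite")


def expected_temperature(climatology: ClimatologyConfig, dates: pd.DatetimeIndex) -> np.ndarray:
    """Noise-free seasonal expectation of the synthetic climatology.

    E[T(d)] = mean + amplitude * cos(2 pi (doy(d) - warmest_day) / 365.25).
    """
    doy = np.asarray(pd.DatetimeIndex(dates).dayofyear, dtype=float)
    phase = 2.0 * np.pi * (doy - climatology.warmest_day_of_year) / DAYS_PER_YEAR
    return climatology.annual_mean + climatology.annual_amplitude * np.cos(phase)


def generate_synthetic_series(
    climatology: ClimatologyConfig, start_date, end_date, site_label: str = "synthetic"
) -> TemperatureSeries:
    """Generate one temperature record per day in [start_date, end_date].

    Gaussian noise of sd ``daily_noise_sd`` is added independently per day;
    the result is bit-for-bit reproducible from ``climatology.rng_seed``.
    """
    start, end = pd.Timestamp(start_date), pd.Timestamp(end_date)
    if start > end:
        raise ValueError(f"reversed date range: {start.date()} > {end.date()}")
    dates = pd.date_range(start, end, freq="D")
    temps = expected_temperature(climatology, dates)
    if climatology.daily_noise_sd > 0:
        rng = np.random.default_rng(climatology.rng_seed)
        temps = temps + rng.normal(0.0, climatology.daily_noise_sd, size=len(dates))
    return TemperatureSeries(dates, temps, site_label)


def apply_scenario(series: TemperatureSeries, scenario: ScenarioConfig) -> TemperatureSeries:
    """Shift every temperature by the scenario's delta_T; dates unchanged."""
    return TemperatureSeries(series.dates, series.values + scenario.delta_T, series.site_label)


def read_temperature_csv(path) -> TemperatureSeries:
    """Read a daily temperature series from CSV.

    The header must name a date column (``date``, case-insensitive) and a
    temperature column (``tmean_air_c``, or any single remaining numeric
    column). Errors name the offending row (1-based, excluding the header).
    """
    df = pd.read_csv(path, dtype=str)
    cols = {c.lower().strip(): c for c in df.columns}
    if DATE_COLUMN not in cols:
        raise ValueError(f"no '{DATE_COLUMN}' column in {path} (found {list(df.columns)})")
    date_col = cols[DATE_COLUMN]
    if TEMP_COLUMN in cols:
        temp_col = cols[TEMP_COLUMN]
    else:
        others = [c for c in df.columns if c != date_col]
        if len(others) != 1:
            raise ValueError(
                f"cannot identify the temperature column in {path}; "
                f"expected '{TEMP_COLUMN}' or exactly one non-date column"
            )
        temp_col = others[0]

    dates = pd.to_datetime(df[date_col], errors="coerce")
    if dates.isna().any():
        row = int(dates.isna().idxmax()) + 1
        raise ValueError(f"unparseable date {df[date_col].iloc[row - 1]!r} at row {row}")
    temps = pd.to_numeric(df[temp_col], errors="coerce")
    if temps.isna().any():
        row = int(temps.isna().idxmax()) + 1
        raise ValueError(f"non-numeric temperature {df[temp_col].iloc[row - 1]!r} at row {row}")
    if dates.duplicated().any():
        row = int(dates.duplicated().idxmax()) + 1
        raise ValueError(f"duplicate date {dates.iloc[row - 1].date()} at row {row}")
    if not dates.is_monotonic_increasing:
        row = int(np.argmax(np.diff(dates.values) < np.timedelta64(0))) + 2
        raise ValueError(f"dates out of order at row {row}")
    return TemperatureSeries(pd.DatetimeIndex(dates), temps.to_numpy(float), site_label=str(path))


def write_temperature_csv(series: TemperatureSeries, path) -> None:
    df = series.to_frame()
    df[DATE_COLUMN] = df[DATE_COLUMN].dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)
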