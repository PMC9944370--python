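"""Micrometeorology processing.

Turns raw half-hourly environmental records into vapour pressure deficit,
dew-point temperature, dew events, calibrated soil moisture and daily
summaries.  The dew-point uses the Magnus approximation with A = 17.625
(dimensionless) and B = 243.04 degC; the matching saturation vapour pressure
coefficient is 0.61094 kPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateFitError, DomainError

__all__ = [
    "MagnusConstants",
    "MeteoRecord",
    "DewEvent",
    "SoilCalibration",
    "saturation_vapour_pressure",
    "vpd",
    "dew_point",
    "detect_dew_events",
    "calibrate_soil_probe",
    "apply_soil_calibration",
    "daily_summaries",
    "meteo_frame",
]

#: Saturation vapour pressure at 0 degC (kPa), consistent with the Magnus
#: constants below.
ESAT_COEFF_KPA = 0.61094

#: Default leaf-wetness resistance threshold for dew detection (kOhm).
DEW_RESISTANCE_THRESHOLD = 400.0

#: Default |T_air - T_dew| window for dew detection (degC).
DEW_TEMP_WINDOW = 0.5


@dataclass(frozen=True)
class MagnusConstants:
    """Magnus-formula constants (overridable, defaults fixed)."""

    A: float = 17.625
    B: float = 243.04  # degC


@dataclass
class MeteoRecord:
    """One half-hourly environmental observation."""

    timestamp: pd.Timestamp
    t_air: float  # degC
    rh: float  # %, in [0, 100]
    rain: float = 0.0  # mm per interval
    wetness_resistance: float = np.nan  # kOhm
    soil_probe_raw: float = np.nan  # probe units
    soil_depth: float = 50.0  # cm, carried as metadata

    def __post_init__(self) -> None:
        self.timestamp = pd.Timestamp(self.timestamp)
        if not (0.0 <= self.rh <= 100.0):
            raise DomainError(f"rh={self.rh} outside [0, 100]")
        if self.rain < 0:
            raise DomainError(f"rain={self.rain} is negative")


@dataclass(frozen=True)
class DewEvent:
    """A contiguous run of dew-flagged intervals."""

    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise DomainError("DewEvent end must be after start")

    @property
    def duration_hours(self) -> float:
        return (self.end - self.start) / timedelta(hours=1)


@dataclass(frozen=True)
class SoilCalibration:
    """Linear probe-output -> gravimetric water content calibration."""

    slope: float  # (g/g) per probe unit
    intercept: float  # g/g
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise DegenerateFitError("calibration needs >= 3 pairs")
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise DomainError(f"r_squared={self.r_squared} outside [0, 1]")


# ---------------------------------------------------------------------------
# scalar/vector thermodynamics


def saturation_vapour_pressure(
    t_air, constants: MagnusConstants = MagnusConstants()
):
    """Saturation vapour pressure (kPa) at air temperature ``t_air`` (degC).

    Magnus form ``e_s = 0.61094 * exp(A*t / (B + t))``; strictly increasing
    in temperature.  Raises :class:`DomainError` for ``t_air <= -B``.
    """
    t = np.asarray(t_air, dtype=float)
    if np.any(t <= -constants.B):
        raise DomainError(f"t_air must exceed {-constants.B} degC")
    out = ESAT_COEFF_KPA * np.exp(constants.A * t / (constants.B + t))
    return out if out.ndim else float(out)


def vpd(t_air, rh, constants: MagnusConstants = MagnusConstants()):
    """Vapour pressure deficit (kPa): ``esat(t) * (1 - rh/100)``."""
    rh_arr = np.asarray(rh, dtype=float)
    if np.any((rh_arr < 0) | (rh_arr > 100)):
        raise DomainError("rh outside [0, 100]")
    out = saturation_vapour_pressure(t_air, constants) * (1.0 - rh_arr / 100.0)
    out = np.asarray(out)
    return out if out.ndim else float(out)


def dew_point(t_air, rh, constants: MagnusConstants = MagnusConstants()):
    """Dew-point temperature (degC) from air temperature and RH (%).

    ``T_dew = B*[ln(RH/100) + A*T/(B+T)] / (A - ln(RH/100) - A*T/(B+T))``.
    Equals ``t_air`` at RH = 100; undefined (DomainError) at RH = 0.
    """
    t = np.asarray(t_air, dtype=float)
    rh_arr = np.asarray(rh, dtype=float)
    if np.any((rh_arr <= 0) | (rh_arr > 100)):
        raise DomainError("rh outside (0, 100]")
    gamma = np.log(rh_arr / 100.0) + constants.A * t / (constants.B + t)
    out = constants.B * gamma / (constants.A - gamma)
    out = np.asarray(out)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# tabular helpers

_METEO_COLUMNS = (
    "timestamp",
    "t_air",
    "rh",
    "rain",
    "wetness_resistance",
    "soil_probe_raw",
    "soil_depth",
)


def meteo_frame(series) -> pd.DataFrame:
    """Coerce a meteo input (DataFrame or iterable of MeteoRecord) to a frame.

    Validates that timestamps are strictly increasing.
    """
    if isinstance(series, pd.DataFrame):
        df = series.copy()
    else:
        records = list(series)
        df = pd.DataFrame(
            {col: [getattr(r, col) for r in records] for col in _METEO_COLUMNS}
        )
    if df.empty:
        return pd.DataFrame(columns=_METEO_COLUMNS)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    ts = df["timestamp"].to_numpy()
    if len(ts) > 1 and not (ts[1:] > ts[:-1]).all():
        raise DomainError("timestamps must be strictly increasing")
    return df


def detect_dew_events(
    series,
    resistance_threshold: float = DEW_RESISTANCE_THRESHOLD,
    temp_window: float = DEW_TEMP_WINDOW,
    constants: MagnusConstants = MagnusConstants(),
) -> list[DewEvent]:
    """Detect dew events in a time-ordered meteo series.

    A record is dew-flagged iff rain == 0, wetness resistance is below
    ``resistance_threshold`` (kOhm), and air temperature is within
    ``temp_window`` degC of the dew point.  Consecutive flagged records merge
    into one event; each event's ``end`` is the end of its last flagged
    interval (last timestamp + the series' sampling step).
    """
    df = meteo_frame(series)
    if df.empty:
        return []
    rh = df["rh"].to_numpy(dtype=float)
    t = df["t_air"].to_numpy(dtype=float)
    ok = rh > 0  # dew point undefined at rh == 0; such records are never dew
    tdew = np.full_like(t, np.nan)
    if ok.any():
        tdew[ok] = dew_point(t[ok], rh[ok], constants)
    flagged = (
        (df["rain"].to_numpy(dtype=float) == 0.0)
        & (df["wetness_resistance"].to_numpy(dtype=float) < resistance_threshold)
        & (np.abs(t - tdew) <= temp_window)
    )

    ts = df["timestamp"].reset_index(drop=True)
    step = (
        ts.diff().dropna().min()
        if len(ts) > 1
        else pd.Timedelta(minutes=30)
    )
    events: list[DewEvent] = []
    i = 0
    n = len(flagged)
    while i < n:
        if flagged[i]:
            j = i
            while j + 1 < n and flagged[j + 1]:
                j += 1
            events.append(DewEvent(start=ts[i], end=ts[j] + step))
            i = j + 1
        else:
            i += 1
    return events


def calibrate_soil_probe(pairs: Sequence[tuple[float, float]]) -> SoilCalibration:
    """OLS calibration of probe output to gravimetric water content (g/g).

    ``pairs`` is a list of (probe_raw, gravimetric) tuples; requires >= 3
    pairs with non-constant probe values.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise DegenerateFitError("need >= 3 (probe, gravimetric) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise DegenerateFitError("constant probe values: cannot fit")
    res = stats.linregress(x, y)
    return SoilCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=len(x),
    )


def apply_soil_calibration(probe_raw, cal: SoilCalibration):
    """Map raw probe output to calibrated gravimetric moisture (g/g)."""
    out = cal.slope * np.asarray(probe_raw, dtype=float) + cal.intercept
    return out if out.ndim else float(out)


def daily_summaries(
    series,
    midday_start: str = "12:00",
    midday_end: str = "14:00",
    expected_per_day: int = 48,
    completeness_threshold: float = 0.8,
    calibration: SoilCalibration | None = None,
) -> pd.DataFrame:
    """One row per calendar day: mean midday VPD, rain total, soil moisture.

    The midday window is 12:00-14:00 local clock (inclusive).  Days with no
    midday records carry NaN for midday VPD; days with fewer than
    ``completeness_threshold`` of ``expected_per_day`` intervals are flagged
    ``incomplete``.
    """
    df = meteo_frame(series)
    if df.empty:
        return pd.DataFrame(
            columns=[
                "date",
                "midday_vpd",
                "rain_total",
                "soil_moisture",
                "n_records",
                "incomplete",
            ]
        )
    df["vpd"] = vpd(df["t_air"].to_numpy(), df["rh"].to_numpy())
    if calibration is not None:
        df["soil_moisture"] = apply_soil_calibration(
            df["soil_probe_raw"].to_numpy(), calibration
        )
    else:
        df["soil_moisture"] = df["soil_probe_raw"]
    df["date"] = df["timestamp"].dt.normalize()
    tod = df["timestamp"].dt.time
    lo = pd.Timestamp(f"2000-01-01 {midday_start}").time()
    hi = pd.Timestamp(f"2000-01-01 {midday_end}").time()
    df["is_midday"] = (tod >= lo) & (tod <= hi)

    def _one_day(g: pd.DataFrame) -> pd.Series:
        midday = g.loc[g["is_midday"], "vpd"]
        return pd.Series(
            {
                "midday_vpd": midday.mean() if len(midday) else np.nan,
                "rain_total": g["rain"].sum(),
                "soil_moisture": g["soil_moisture"].mean(),
                "n_records": len(g),
                "incomplete": len(g) < completeness_threshold * expected_per_day,
            }
        )

    out = df.groupby("date", sort=True).apply(_one_day, include_groups=False)
    out = out.reset_index()
    out["n_records"] = out["n_records"].astype(int)
    out["incomplete"] = out["incomplete"].astype(bool)
    return out
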