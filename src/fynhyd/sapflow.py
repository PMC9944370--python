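"""Heat-ratio sap-flow processing.

Chain: half-hourly heat ratios -> heat pulse velocity (vh, cm s-1) -> sap
velocity / sap flux density (Js, g cm-2 s-1) -> sap-flow-derived
transpiration (Esf, mmol m-2 s-1) via a per-individual midday vh~E
regression -> sap-flow-derived stomatal conductance (Gsf, mmol m-2 s-1)
from Esf and VPD, plus daily totals and reference-period normalization.

The vh equation is ``vh = (k/x) * ln(heat_ratio)`` with thermal diffusivity
``k`` (cm2 s-1) and probe spacing ``x`` (cm); downstream vh -> vs -> Js
conversions are linear factors defaulting to identity, and an optional
multiplicative wound-correction factor is exposed.  Gsf is computed as
``alpha * Esf / VPD`` with ``alpha = rho_w * G_v * T_kelvin`` as printed;
because every acceptance surface is normalized to a reference period, the
value of alpha cancels.  A standard-form switch (``alpha = P_atm``) is
available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateFitError,
    DomainError,
    IdMismatchError,
    InvalidConfigError,
)

__all__ = [
    "GaugeCalibration",
    "PhysicalConstants",
    "VhToEMap",
    "heat_pulse_velocity",
    "sap_flux_density",
    "total_daily_js",
    "fit_vh_to_E",
    "transpiration_from_sapflow",
    "gsf",
    "normalize_to_reference",
]

DEFAULT_VPD_FLOOR_KPA = 0.1


@dataclass(frozen=True)
class GaugeCalibration:
    """Gauge constants for the heat-ratio conversion chain.

    Defaults are identity factors; real deployments override them with
    sensor-specific values.
    """

    thermal_diffusivity_k: float = 1.0  # cm2 s-1
    probe_spacing_x: float = 1.0  # cm
    vh_to_vs_factor: float = 1.0
    vs_to_js_factor: float = 1.0  # g cm-3
    wound_correction: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "thermal_diffusivity_k",
            "probe_spacing_x",
            "vh_to_vs_factor",
            "vs_to_js_factor",
            "wound_correction",
        ):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")


@dataclass(frozen=True)
class PhysicalConstants:
    rho_w: float = 1000.0  # kg m-3
    g_v: float = 0.462  # m3 kPa kg-1 K-1, gas constant for water vapour
    p_atm: float = 101.325  # kPa, used by the standard-form alpha switch


@dataclass(frozen=True)
class VhToEMap:
    """Per-individual linear map from midday vh to transpiration E."""

    slope: float  # (mmol m-2 s-1) / (cm s-1)
    intercept: float  # mmol m-2 s-1
    r_squared: float
    individual_id: str


def heat_pulse_velocity(heat_ratio, cal: GaugeCalibration = GaugeCalibration()):
    """Heat pulse velocity vh (cm s-1) from a downstream/upstream heat ratio.

    ``vh = (k / x) * ln(ratio) * wound_correction``; ratio 1 gives zero flow,
    ratios below 1 give negative (reverse) flow.
    """
    ratio = np.asarray(heat_ratio, dtype=float)
    if np.any(ratio <= 0):
        raise DomainError("heat ratio must be positive")
    out = (
        cal.thermal_diffusivity_k
        / cal.probe_spacing_x
        * np.log(ratio)
        * cal.wound_correction
    )
    return out if out.ndim else float(out)


def sap_flux_density(vh, cal: GaugeCalibration = GaugeCalibration()):
    """Sap flux density Js (g cm-2 s-1) from vh via linear gauge factors."""
    if cal is None:
        raise InvalidConfigError("gauge calibration required")
    out = np.asarray(vh, dtype=float) * cal.vh_to_vs_factor * cal.vs_to_js_factor
    return out if out.ndim else float(out)


def total_daily_js(
    js: pd.Series,
    max_missing_fraction: float = 0.10,
    expected_per_day: int = 48,
) -> pd.Series:
    """Total daily Js (g cm-2 day-1): sum of js * dt over each calendar day.

    ``js`` is indexed by timestamp; the interval dt is inferred from the
    median spacing.  Days missing more than ``max_missing_fraction`` of the
    expected half-hours come back NaN.
    """
    js = js.sort_index()
    idx = pd.DatetimeIndex(js.index)
    if len(idx) > 1:
        dt_seconds = float(
            pd.Series(idx).diff().dropna().median() / pd.Timedelta(seconds=1)
        )
    else:
        dt_seconds = 1800.0
    per_day = js.groupby(idx.normalize())
    totals = per_day.sum() * dt_seconds
    counts = per_day.count()
    min_count = (1.0 - max_missing_fraction) * expected_per_day
    totals[counts < min_count] = np.nan
    totals.index.name = "date"
    totals.name = "total_daily_js"
    return totals


def fit_vh_to_E(pairs: Sequence[tuple[float, float]], individual_id: str = "") -> VhToEMap:
    """Least-squares linear map from midday (vh, E) pairs; >= 3 required."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise DegenerateFitError("need >= 3 midday (vh, E) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise DegenerateFitError("constant vh: cannot fit vh -> E map")
    res = stats.linregress(x, y)
    return VhToEMap(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        individual_id=individual_id,
    )


def transpiration_from_sapflow(vh, vmap: VhToEMap, individual_id: str | None = None):
    """Esf (mmol m-2 s-1) = slope * vh + intercept, floored at zero."""
    if individual_id is not None and vmap.individual_id and individual_id != vmap.individual_id:
        raise IdMismatchError(
            f"map fitted for {vmap.individual_id!r}, applied to {individual_id!r}"
        )
    out = np.maximum(np.asarray(vh, dtype=float) * vmap.slope + vmap.intercept, 0.0)
    return out if out.ndim else float(out)


def gsf(
    esf,
    vpd,
    t_air,
    constants: PhysicalConstants = PhysicalConstants(),
    vpd_floor: float = DEFAULT_VPD_FLOOR_KPA,
    alpha_form: Literal["rho-gv-t", "p-atm"] = "rho-gv-t",
):
    """Sap-flow-derived stomatal conductance Gsf (mmol m-2 s-1).

    ``gsf = alpha * esf / vpd``.  With ``alpha_form="rho-gv-t"`` (default)
    alpha = rho_w * G_v * (t_air + 273.15) as printed; ``"p-atm"`` uses
    standard atmospheric pressure instead.  Records with vpd <= ``vpd_floor``
    are masked to NaN rather than dividing by a near-zero demand.
    """
    esf_arr = np.asarray(esf, dtype=float)
    vpd_arr = np.asarray(vpd, dtype=float)
    t_arr = np.asarray(t_air, dtype=float)
    if alpha_form == "rho-gv-t":
        alpha = constants.rho_w * constants.g_v * (t_arr + 273.15)
    elif alpha_form == "p-atm":
        alpha = constants.p_atm
    else:
        raise InvalidConfigError(f"unknown alpha_form {alpha_form!r}")
    masked = vpd_arr <= vpd_floor
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(masked, np.nan, alpha * esf_arr / np.where(masked, 1.0, vpd_arr))
    out = np.asarray(out)
    return out if out.ndim else float(out)


def normalize_to_reference(
    daily: pd.Series,
    reference_window: tuple,
    statistic: Literal["mean", "max"] = "mean",
    min_reference_days: int = 5,
) -> pd.Series:
    """Express a daily series as percent of its reference-period statistic.

    ``reference_window`` is an inclusive (start, end) date pair; the
    reference statistic (mean by default, max by config) is taken over valid
    days in the window, which must contain at least ``min_reference_days``
    of them.
    """
    daily = daily.sort_index()
    start, end = (pd.Timestamp(reference_window[0]), pd.Timestamp(reference_window[1]))
    window = daily.loc[(daily.index >= start) & (daily.index <= end)].dropna()
    if len(window) < min_reference_days:
        raise InvalidConfigError(
            f"reference window has {len(window)} valid days; "
            f"need >= {min_reference_days}"
        )
    ref = float(window.mean() if statistic == "mean" else window.max())
    if ref == 0:
        raise InvalidConfigError("reference statistic is zero; cannot normalize")
    out = daily / ref * 100.0
    out.name = f"{daily.name or 'value'}_pct_of_reference"
    return out
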