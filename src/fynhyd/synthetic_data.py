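"""Synthetic fixtures for every downstream stage.

Generates (i) half-hourly weather with pulsed rainfall, diel temperature /
humidity cycles and labelled dew nights; (ii) bucket-model soil moisture;
(iii) species plant-response series (heat-pulse velocity, water potentials,
stomatal conductance) for three growth-form archetypes; and (iv) drying
image stacks whose vessels embolize according to the embolism sigmoid, so
the optical pipeline can be validated end to end against known parameters.

Every generator is a pure function of (config, seed): the same config run
twice yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, DomainError, InvalidConfigError
from .micromet import MeteoRecord, dew_point
from .micromet import vpd as compute_vpd
from .vulnerability import ImageStack, PsiTimeline

__all__ = [
    "WeatherConfig",
    "BucketModel",
    "SpeciesArchetype",
    "SyntheticStackConfig",
    "SyntheticStack",
    "PlantSeries",
    "ERICOID",
    "PROTEOID",
    "RESTIOID",
    "generate_weather",
    "generate_soil_moisture",
    "generate_soil_layers",
    "generate_plant_series",
    "generate_optical_stack",
    "pulse_response_ratio",
    "write_weather_csv",
    "write_stack",
]

HALF_HOURS_PER_DAY = 48


@dataclass(frozen=True)
class WeatherConfig:
    """Season-scale weather generator settings."""

    season_length_days: int = 90
    summer_rain_total: float = 90.0  # mm
    n_large_events: int = 0  # events > 20 mm
    small_event_rate: float = 1.0  # events/week, each < 10 mm
    diel_t_range: float = 12.0  # degC peak-to-trough
    diel_rh_range: float = 40.0  # % peak-to-trough
    dew_probability_per_night: float = 0.3
    t_mean: float = 20.0  # degC season mean
    rh_mean: float = 55.0  # % season mean
    large_event_fractions: tuple = (0.25, 0.5, 0.75)  # season positions
    start: str = "2013-12-01"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.season_length_days <= 0:
            raise InvalidConfigError("season_length_days must be positive")
        if self.summer_rain_total < 0:
            raise InvalidConfigError("summer_rain_total must be non-negative")
        if not (0.0 <= self.dew_probability_per_night <= 1.0):
            raise InvalidConfigError("dew_probability_per_night outside [0, 1]")
        if self.n_large_events < 0 or self.small_event_rate < 0:
            raise InvalidConfigError("event counts/rates must be non-negative")


@dataclass(frozen=True)
class BucketModel:
    """Single-layer soil water bucket (volumetric %)."""

    capacity: float = 30.0  # %
    residual: float = 5.0  # %
    infiltration_fraction: float = 0.5  # % moisture per mm rain
    drainage_rate: float = 0.08  # day-1
    evapotranspiration_coupling: float = 0.0  # extra day-1 loss

    def __post_init__(self) -> None:
        if self.residual > self.capacity:
            raise InvalidConfigError("residual must not exceed capacity")
        if self.drainage_rate < 0 or self.evapotranspiration_coupling < 0:
            raise InvalidConfigError("loss rates must be non-negative")


@dataclass(frozen=True)
class SpeciesArchetype:
    """Simulation parameters for one growth-form response type."""

    name: str
    rooting_depth_weighting: float  # 1 = fully shallow, 0 = fully deep
    vpd_sensitivity: float  # dimensionless
    soil_sensitivity: float  # shape of the psi(soil) response
    dew_use_fraction: float
    max_vh: float  # cm s-1
    psi_min_dry: float  # MPa, most negative predawn under full drydown
    vulnerability_a: float  # MPa-1, negative
    vulnerability_b: float  # MPa, P50
    midday_drawdown_per_kpa: float = 0.3  # MPa of extra tension per kPa VPD

    def __post_init__(self) -> None:
        if self.vulnerability_a >= 0:
            raise InvalidConfigError("vulnerability_a must be negative")
        if self.psi_min_dry >= 0:
            raise InvalidConfigError("psi_min_dry must be negative")
        if self.max_vh < 0:
            raise InvalidConfigError("max_vh must be non-negative")
        if not (0.0 <= self.rooting_depth_weighting <= 1.0):
            raise InvalidConfigError("rooting_depth_weighting outside [0, 1]")


# Default archetypes for the three fynbos growth forms.  Water-potential
# floors and P50 values follow the study-site species they emulate.
ERICOID = SpeciesArchetype(
    name="ericoid",
    rooting_depth_weighting=1.0,
    vpd_sensitivity=0.5,
    soil_sensitivity=1.5,
    dew_use_fraction=0.0,
    max_vh=0.02,
    psi_min_dry=-4.0,
    vulnerability_a=-1.51,
    vulnerability_b=-5.68,
    midday_drawdown_per_kpa=0.35,
)
PROTEOID = SpeciesArchetype(
    name="proteoid",
    rooting_depth_weighting=0.0,
    vpd_sensitivity=1.2,
    soil_sensitivity=1.0,
    dew_use_fraction=0.0,
    max_vh=0.015,
    psi_min_dry=-1.5,
    vulnerability_a=-3.0,
    vulnerability_b=-3.50,
    midday_drawdown_per_kpa=0.15,
)
RESTIOID = SpeciesArchetype(
    name="restioid",
    rooting_depth_weighting=0.8,
    vpd_sensitivity=0.8,
    soil_sensitivity=1.2,
    dew_use_fraction=0.3,
    max_vh=0.025,
    psi_min_dry=-1.9,
    vulnerability_a=-10.0,
    vulnerability_b=-2.30,
    midday_drawdown_per_kpa=0.2,
)


# ---------------------------------------------------------------------------
# weather


def _diel_cycle(hours: np.ndarray, peak_hour: float) -> np.ndarray:
    """Unit cosine peaking at ``peak_hour`` local time."""
    return np.cos(2.0 * np.pi * (hours - peak_hour) / 24.0)


def generate_weather(config: WeatherConfig) -> pd.DataFrame:
    """Generate a half-hourly weather table for one season.

    Columns: timestamp, t_air, rh, rain, wetness_resistance, soil_probe_raw
    (NaN; filled by the soil generator), soil_depth, dew_truth (generator
    labels for dew intervals).  Rainfall sums exactly to
    ``summer_rain_total``; dew intervals satisfy the dew-detection rule
    (resistance < 400 kOhm, |T - T_dew| <= 0.5 degC, rain == 0).
    """
    rng = np.random.default_rng(config.seed)
    n = config.season_length_days * HALF_HOURS_PER_DAY
    timestamps = pd.date_range(config.start, periods=n, freq="30min")
    hours = timestamps.hour.to_numpy() + timestamps.minute.to_numpy() / 60.0
    day_index = np.arange(n) // HALF_HOURS_PER_DAY

    # temperature peaks at 14:00, humidity in anti-phase (early morning peak)
    t_air = (
        config.t_mean
        + 0.5 * config.diel_t_range * _diel_cycle(hours, peak_hour=14.0)
        + rng.normal(0.0, 0.4, n)
        + np.repeat(rng.normal(0.0, 1.5, config.season_length_days), HALF_HOURS_PER_DAY)
    )
    rh = (
        config.rh_mean
        + 0.5 * config.diel_rh_range * _diel_cycle(hours, peak_hour=4.0)
        + rng.normal(0.0, 2.0, n)
    )
    rh = np.clip(rh, 5.0, 100.0)

    rain = _generate_rain(config, rng, n, day_index)

    # dew nights: a contiguous pre-dawn window with high RH, low wetness
    # resistance and T pinned close to the dew point
    dew_truth = np.zeros(n, dtype=bool)
    wetness = rng.uniform(1000.0, 10000.0, n)
    night_starts = np.flatnonzero(hours == 2.0)
    for s in night_starts:
        if rng.random() >= config.dew_probability_per_night:
            continue
        length = int(rng.integers(4, 9))  # 2-4 h of dew
        sl = slice(s, min(s + length, n))
        if rain[sl].sum() > 0:
            continue  # dew events exclude rainy intervals
        rh[sl] = rng.uniform(98.5, 100.0, sl.stop - sl.start)
        wetness[sl] = rng.uniform(50.0, 350.0, sl.stop - sl.start)
        dew_truth[sl] = True
    # pin dew-interval temperature within the detection window of T_dew
    if dew_truth.any():
        tdew = dew_point(t_air[dew_truth], rh[dew_truth])
        t_air[dew_truth] = tdew + 0.2  # well inside the 0.5 degC window

    return pd.DataFrame(
        {
            "timestamp": timestamps,
            "t_air": t_air,
            "rh": rh,
            "rain": rain,
            "wetness_resistance": wetness,
            "soil_probe_raw": np.nan,
            "soil_depth": 50.0,
            "dew_truth": dew_truth,
        }
    )


def _generate_rain(
    config: WeatherConfig, rng: np.random.Generator, n: int, day_index: np.ndarray
) -> np.ndarray:
    """Pulsed rainfall: fixed-position large events plus Bernoulli small ones."""
    rain = np.zeros(n)
    if config.summer_rain_total == 0:
        return rain
    n_days = config.season_length_days
    amounts = []
    positions = []
    for i in range(config.n_large_events):
        frac = config.large_event_fractions[i % len(config.large_event_fractions)]
        day = min(int(frac * n_days), n_days - 1)
        positions.append(day)
        amounts.append(rng.uniform(22.0, 35.0))
    p_small = min(config.small_event_rate / 7.0, 1.0)
    for day in range(n_days):
        if day in positions:
            continue
        if rng.random() < p_small:
            positions.append(day)
            amounts.append(rng.uniform(1.0, 9.0))
    if not positions:  # guarantee at least one event carries the total
        positions = [n_days // 2]
        amounts = [config.summer_rain_total]
    amounts = np.asarray(amounts, dtype=float)
    amounts *= config.summer_rain_total / amounts.sum()
    for day, amount in zip(positions, amounts):
        # spread each event over a few afternoon half-hours
        start = day * HALF_HOURS_PER_DAY + 30  # ~15:00
        width = int(rng.integers(2, 6))
        weights = rng.uniform(0.5, 1.0, width)
        weights /= weights.sum()
        for k in range(width):
            idx = min(start + k, n - 1)
            rain[idx] += amount * weights[k]
    return rain


# ---------------------------------------------------------------------------
# soil


def generate_soil_moisture(
    rain: pd.Series | np.ndarray,
    bucket: BucketModel,
    dt_days: float = 1.0 / HALF_HOURS_PER_DAY,
    initial: float | None = None,
) -> pd.Series:
    """Integrate the soil bucket over a rainfall series.

    Per step: exponential relaxation toward ``residual`` at rate
    ``drainage_rate + evapotranspiration_coupling`` (day-1), then an
    infiltration gain of ``infiltration_fraction`` moisture-% per mm of
    rain, clipped to ``capacity``.  With zero rain the series decays in
    closed form: ``residual + (s0 - residual) * exp(-rate * t)``.
    """
    values = np.asarray(rain, dtype=float)
    if np.any(values < 0):
        raise DomainError("rain must be non-negative")
    if bucket.residual >= bucket.capacity:
        # degenerate bucket: residual == capacity pins the series
        if bucket.residual > bucket.capacity:
            raise InvalidConfigError("residual must not exceed capacity")
        out = np.full(len(values), bucket.capacity)
        return _soil_series(out, rain)
    rate = bucket.drainage_rate + bucket.evapotranspiration_coupling
    decay = np.exp(-rate * dt_days)
    s = bucket.capacity if initial is None else float(initial)
    s = min(max(s, bucket.residual), bucket.capacity)
    out = np.empty(len(values))
    for i, r in enumerate(values):
        s = bucket.residual + (s - bucket.residual) * decay
        s = min(s + bucket.infiltration_fraction * r, bucket.capacity)
        out[i] = s
    return _soil_series(out, rain)


def _soil_series(values: np.ndarray, rain) -> pd.Series:
    index = rain.index if isinstance(rain, pd.Series) else pd.RangeIndex(len(values))
    return pd.Series(values, index=index, name="soil_moisture")


def generate_soil_layers(
    rain: pd.Series,
    shallow: BucketModel | None = None,
    deep: BucketModel | None = None,
) -> pd.DataFrame:
    """Two-layer soil: a flashy shallow bucket and a damped deep bucket."""
    shallow = shallow or BucketModel(
        capacity=25.0, residual=3.0, infiltration_fraction=0.8, drainage_rate=0.15
    )
    deep = deep or BucketModel(
        capacity=35.0,
        residual=15.0,
        infiltration_fraction=0.05,
        drainage_rate=0.01,
    )
    return pd.DataFrame(
        {
            "shallow": generate_soil_moisture(rain, shallow),
            "deep": generate_soil_moisture(rain, deep),
        }
    )


# ---------------------------------------------------------------------------
# plant response


@dataclass
class PlantSeries:
    """Generated per-individual plant response bundle."""

    vh: pd.Series  # half-hourly heat pulse velocity, cm s-1
    psi: pd.DataFrame  # campaign rows: date, individual_id, species, period, psi
    gs: pd.DataFrame  # campaign rows: date, species, gs (mol m-2 s-1)
    archetype: SpeciesArchetype


def _relative_moisture(series: pd.Series, lo: float, hi: float) -> np.ndarray:
    if hi <= lo:
        return np.ones(len(series))
    return np.clip((series.to_numpy(dtype=float) - lo) / (hi - lo), 0.0, 1.0)


def generate_plant_series(
    archetype: SpeciesArchetype,
    weather: pd.DataFrame,
    soil: pd.DataFrame | pd.Series,
    seed: int = 0,
    campaign_every_days: int = 7,
    n_individuals: int = 5,
    psi_noise_sd: float = 0.05,
    soil_bounds: tuple[float, float] | None = None,
) -> PlantSeries:
    """Generate vh, water-potential campaigns and gs for one archetype.

    Predawn psi is a saturating function of root-weighted relative soil
    moisture (plus a dew credit for dew-using archetypes); midday psi is
    predawn minus a VPD-scaled drawdown, so predawn >= midday always.  vh
    follows a daylight cycle scaled by soil availability and damped by VPD
    sensitivity.
    """
    if isinstance(soil, pd.Series):
        soil = pd.DataFrame({"shallow": soil, "deep": soil})
    if len(weather) != len(soil):
        raise AlignmentError("weather and soil time bases differ in length")
    ts_w = pd.to_datetime(weather["timestamp"]).to_numpy()
    if not np.array_equal(ts_w, soil.index.to_numpy()):
        raise AlignmentError("weather and soil timestamps differ")

    rng = np.random.default_rng(seed)
    timestamps = pd.DatetimeIndex(ts_w)
    w = archetype.rooting_depth_weighting
    if soil_bounds is None:
        lo = min(soil["shallow"].min(), soil["deep"].min())
        hi = max(soil["shallow"].max(), soil["deep"].max())
    else:
        lo, hi = soil_bounds
    theta = w * _relative_moisture(soil["shallow"], lo, hi) + (1.0 - w) * _relative_moisture(
        soil["deep"], lo, hi
    )

    dew = (
        weather["dew_truth"].to_numpy(dtype=bool)
        if "dew_truth" in weather
        else np.zeros(len(weather), dtype=bool)
    )
    # dew credit: a dew night boosts that day's effective moisture
    day_idx = np.arange(len(weather)) // HALF_HOURS_PER_DAY
    dew_day = np.zeros(day_idx.max() + 1, dtype=bool)
    np.maximum.at(dew_day, day_idx, dew)
    theta_eff = np.clip(
        theta + archetype.dew_use_fraction * 0.2 * dew_day[day_idx], 0.0, 1.0
    )

    vpd_series = compute_vpd(weather["t_air"].to_numpy(), weather["rh"].to_numpy())

    # predawn psi: saturating map from effective moisture down to psi_min_dry
    predawn = archetype.psi_min_dry * (1.0 - theta_eff) ** archetype.soil_sensitivity
    drawdown = archetype.midday_drawdown_per_kpa * vpd_series
    midday = predawn - drawdown

    # vh: daylight envelope * soil supply * VPD-damped demand
    hours = timestamps.hour.to_numpy() + timestamps.minute.to_numpy() / 60.0
    daylight = np.clip(np.sin(np.pi * (hours - 6.0) / 12.0), 0.0, None)
    demand = vpd_series / (vpd_series + archetype.vpd_sensitivity)
    supply = np.maximum(theta_eff, 0.01)
    vh_values = archetype.max_vh * daylight * supply * demand
    if archetype.max_vh > 0:
        vh_values = vh_values * np.exp(rng.normal(0.0, 0.05, len(vh_values)))
    vh = pd.Series(vh_values, index=timestamps, name="vh")

    # campaign observations
    campaign_days = np.unique(timestamps.normalize())[::campaign_every_days]
    psi_rows = []
    gs_rows = []
    for date in campaign_days:
        mask_day = timestamps.normalize() == date
        pd_mask = mask_day & (hours >= 4.0) & (hours < 5.0)
        md_mask = mask_day & (hours >= 12.0) & (hours < 14.0)
        if not pd_mask.any() or not md_mask.any():
            continue
        pd_value = float(np.mean(predawn[pd_mask]))
        md_value = float(np.mean(midday[md_mask]))
        for i in range(n_individuals):
            eps_pd = rng.normal(0.0, psi_noise_sd)
            eps_md = rng.normal(0.0, psi_noise_sd)
            psi_rows.append(
                {
                    "date": pd.Timestamp(date),
                    "individual_id": f"{archetype.name}-{i + 1}",
                    "species": archetype.name,
                    "period": "predawn",
                    "psi": min(pd_value + eps_pd, 0.0),
                }
            )
            psi_rows.append(
                {
                    "date": pd.Timestamp(date),
                    "individual_id": f"{archetype.name}-{i + 1}",
                    "species": archetype.name,
                    "period": "midday",
                    "psi": min(md_value + eps_md, min(pd_value + eps_pd, 0.0)),
                }
            )
        gs_rows.append(
            {
                "date": pd.Timestamp(date),
                "species": archetype.name,
                "gs": float(
                    0.3 * np.mean(supply[md_mask]) * np.mean(demand[md_mask])
                ),
            }
        )
    return PlantSeries(
        vh=vh,
        psi=pd.DataFrame(psi_rows),
        gs=pd.DataFrame(gs_rows),
        archetype=archetype,
    )


def pulse_response_ratio(
    vh: pd.Series,
    pulse_date,
    pre_days: int = 10,
    post_days: int = 4,
) -> float:
    """Fold change of total daily vh after a rain pulse vs the dry spell before.

    Ratio of the maximum daily total in the ``post_days`` window following
    the pulse to the mean daily total over the ``pre_days`` before it.
    """
    pulse_date = pd.Timestamp(pulse_date).normalize()
    daily = vh.groupby(pd.DatetimeIndex(vh.index).normalize()).sum()
    pre = daily.loc[
        (daily.index >= pulse_date - pd.Timedelta(days=pre_days))
        & (daily.index < pulse_date)
    ]
    post = daily.loc[
        (daily.index > pulse_date)
        & (daily.index <= pulse_date + pd.Timedelta(days=post_days))
    ]
    if pre.empty or post.empty or pre.mean() == 0:
        raise DomainError("pulse windows empty or zero baseline")
    return float(post.max() / pre.mean())


# ---------------------------------------------------------------------------
# optical stacks


@dataclass(frozen=True)
class SyntheticStackConfig:
    """Drying image-stack generator settings."""

    image_shape: tuple[int, int] = (120, 120)
    n_vessels: int = 100
    vulnerability_a: float = -2.0  # MPa-1
    vulnerability_b: float = -3.0  # MPa (P50)
    psi_start: float = 0.0  # MPa
    psi_end: float = -8.0  # MPa
    n_frames: int = 80
    vessel_px: tuple[int, int] = (3, 4)  # vessel footprint, rows x cols
    background_grey: int = 100
    embolized_grey: int = 180
    noise_sd: float = 0.0
    start: str = "2020-12-01"
    frame_minutes: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vessels < 1:
            raise InvalidConfigError("n_vessels must be >= 1")
        if self.vulnerability_a >= 0:
            raise InvalidConfigError("vulnerability_a must be negative")
        if self.psi_end > self.psi_start:
            raise InvalidConfigError("drying schedule must be non-increasing")
        if self.n_frames < 2:
            raise InvalidConfigError("need >= 2 frames")


@dataclass
class SyntheticStack:
    """Generated stack plus the ground truth used to build it."""

    stack: ImageStack
    timeline: PsiTimeline
    vessel_psi: np.ndarray  # true embolism psi per vessel
    vessel_masks: np.ndarray  # (n_vessels, h, w) bool
    config: SyntheticStackConfig


def _draw_vessel_psi(
    rng: np.random.Generator, n: int, a: float, b: float
) -> np.ndarray:
    """Inverse-CDF draws of per-vessel embolism potentials from the sigmoid.

    The fraction of vessels embolized by potential psi is
    ``1 - 1/(1 + e^{a(psi-b)})``, so ``psi = b + ln(u/(1-u))/a``.
    """
    u = rng.uniform(1e-9, 1.0 - 1e-9, n)
    return b + np.log(u / (1.0 - u)) / a


def generate_optical_stack(config: SyntheticStackConfig) -> SyntheticStack:
    """Generate a drying image stack with known embolism ground truth.

    Vessels are disjoint rectangles on a grid; each flips from background to
    embolized grey exactly once, at the first frame where the drying
    schedule reaches its drawn embolism potential.  Vessels whose potential
    falls outside the schedule span are clamped to the nearest frame so the
    final frame always shows 100% of vessel pixels embolized.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_shape
    vr, vc = config.vessel_px
    gap = 2
    cols = max((w - gap) // (vc + gap), 1)
    rows = max((h - gap) // (vr + gap), 1)
    if rows * cols < config.n_vessels:
        raise InvalidConfigError(
            f"image too small for {config.n_vessels} vessels ({rows * cols} slots)"
        )
    slots = rng.choice(rows * cols, size=config.n_vessels, replace=False)

    vessel_masks = np.zeros((config.n_vessels, h, w), dtype=bool)
    for i, slot in enumerate(slots):
        r, c = divmod(int(slot), cols)
        r0 = gap + r * (vr + gap)
        c0 = gap + c * (vc + gap)
        vessel_masks[i, r0 : r0 + vr, c0 : c0 + vc] = True

    psi_v = _draw_vessel_psi(
        rng, config.n_vessels, config.vulnerability_a, config.vulnerability_b
    )
    schedule = np.linspace(config.psi_start, config.psi_end, config.n_frames)
    # first frame at which the schedule has reached each vessel's potential;
    # clamp so every vessel embolizes within the run (frame 0 excluded so
    # the flip is visible in a difference frame)
    flip_frame = np.argmax(schedule[None, :] <= psi_v[:, None], axis=1)
    flip_frame[psi_v > schedule[0]] = 1
    flip_frame[psi_v < schedule[-1]] = config.n_frames - 1
    flip_frame = np.clip(flip_frame, 1, config.n_frames - 1)

    frames = np.empty((config.n_frames, h, w), dtype=np.uint8)
    base = np.full((h, w), float(config.background_grey))
    for t in range(config.n_frames):
        img = base.copy()
        for i in range(config.n_vessels):
            if t >= flip_frame[i]:
                img[vessel_masks[i]] = config.embolized_grey
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, (h, w))
        frames[t] = np.clip(np.round(img), 0, 255).astype(np.uint8)

    timestamps = pd.date_range(
        config.start, periods=config.n_frames, freq=pd.Timedelta(minutes=config.frame_minutes)
    )
    stack = ImageStack(frames=frames, timestamps=timestamps, sample_id=f"synthetic-{config.seed}")
    timeline = PsiTimeline(timestamps=timestamps, psi=np.minimum(schedule, 0.0))
    return SyntheticStack(
        stack=stack,
        timeline=timeline,
        vessel_psi=psi_v,
        vessel_masks=vessel_masks,
        config=config,
    )


# ---------------------------------------------------------------------------
# fixture writers


def write_weather_csv(weather: pd.DataFrame, path) -> Path:
    """Write the meteo table as CSV with ISO-8601 timestamps."""
    path = Path(path)
    out = weather.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    out.to_csv(path, index=False)
    return path


def write_stack(synth: SyntheticStack, directory) -> Path:
    """Write numbered 8-bit grayscale TIFFs plus a timestamp manifest CSV."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for i, frame in enumerate(synth.stack.frames):
        name = f"frame_{i:04d}.tif"
        tifffile.imwrite(directory / name, frame.astype(np.uint8))
        names.append(name)
    manifest = pd.DataFrame(
        {
            "filename": names,
            "timestamp": synth.stack.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
        }
    )
    manifest.to_csv(directory / "manifest.csv", index=False)
    pd.DataFrame(
        {
            "timestamp": synth.timeline.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
            "psi": synth.timeline.psi,
        }
    ).to_csv(directory / "psi_timeline.csv", index=False)
    return directory


def weather_records(weather: pd.DataFrame) -> list[MeteoRecord]:
    """View a weather frame as MeteoRecord objects (micromet input type)."""
    return [
        MeteoRecord(
            timestamp=row.timestamp,
            t_air=row.t_air,
            rh=row.rh,
            rain=row.rain,
            wetness_resistance=row.wetness_resistance,
            soil_probe_raw=row.soil_probe_raw,
            soil_depth=row.soil_depth,
        )
        for row in weather.itertuples()
    ]
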