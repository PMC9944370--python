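"""Optical xylem vulnerability curves.

Workflow: a drying sample is imaged repeatedly; consecutive frames are
subtracted so that each embolism event appears as a bright local change;
events are thresholded and counted as connected pixel clusters; cumulative
embolized pixels, expressed as percent of the final total and paired with
the water-potential timeline, give the vulnerability curve, modelled as

    percent_embolism(psi) = 100 - 100 / (1 + exp(a * (psi - b)))

with slope parameter ``a`` (MPa-1, negative) and ``b`` the water potential
at 50% embolism (P50, MPa).  Derived metrics: predicted in-situ loss of
function (the curve evaluated at the seasonal minimum water potential) and
the hydraulic safety margin (psi_min - P50).
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .errors import (
    DegenerateFitError,
    DomainError,
    ExtrapolationError,
    FitError,
    InvalidConfigError,
    StackError,
)

__all__ = [
    "ImageStack",
    "EmbolismEventMap",
    "PsiTimeline",
    "VulnerabilityCurve",
    "sigmoid_percent_embolism",
    "slope_from_point",
    "difference_images",
    "detect_embolism_events",
    "cumulative_embolism",
    "psi_at_time",
    "fit_vulnerability_curve",
    "species_curve",
    "predicted_loss",
    "round_half_up",
    "safety_margin",
    "default_intensity_threshold",
]

DEFAULT_MIN_CLUSTER_PX = 10

#: 8-connectivity structuring element for event clustering.
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


@dataclass
class ImageStack:
    """Ordered grayscale frames of identical shape with timestamps."""

    frames: np.ndarray  # (n_frames, h, w)
    timestamps: pd.DatetimeIndex
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise StackError("frames must be a (n, h, w) array")
        if self.frames.shape[0] < 2:
            raise StackError("need >= 2 frames")
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        if len(self.timestamps) != self.frames.shape[0]:
            raise StackError("one timestamp per frame required")
        ts = self.timestamps.to_numpy()
        if not (ts[1:] > ts[:-1]).all():
            raise StackError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class EmbolismEventMap:
    """Per-difference-frame masks of newly embolized pixels."""

    masks: np.ndarray  # (n_frames-1, h, w) bool, disjoint per pixel
    timestamps: pd.DatetimeIndex  # one per difference frame
    n_events_per_frame: np.ndarray  # cluster counts

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        # a pixel embolizes at most once
        if np.any(self.masks.sum(axis=0) > 1):
            raise StackError("event masks overlap: pixel embolized twice")

    @property
    def counts(self) -> np.ndarray:
        """Newly embolized pixels per frame."""
        return self.masks.sum(axis=(1, 2))

    @property
    def total_pixels(self) -> int:
        return int(self.masks.sum())

    @property
    def total_events(self) -> int:
        return int(self.n_events_per_frame.sum())


@dataclass
class PsiTimeline:
    """Water-potential observations (MPa, negative under tension) over time."""

    timestamps: pd.DatetimeIndex
    psi: np.ndarray  # MPa, <= 0

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.psi = np.asarray(self.psi, dtype=float)
        if len(self.timestamps) != len(self.psi):
            raise InvalidConfigError("timeline lengths differ")
        if np.any(self.psi > 0):
            raise DomainError(
                "psi must be <= 0 MPa; positive 'tension' units are rejected"
            )
        ts = self.timestamps.to_numpy()
        if len(ts) > 1 and not (ts[1:] > ts[:-1]).all():
            raise InvalidConfigError("timeline timestamps must be increasing")
        # drying run: non-increasing up to 0.1 MPa observation noise
        if len(self.psi) > 1 and np.any(np.diff(self.psi) > 0.1):
            raise InvalidConfigError("psi timeline rises by more than 0.1 MPa")


@dataclass(frozen=True)
class VulnerabilityCurve:
    """Fitted sigmoid (a, b); ``b`` is P50 by construction."""

    a: float  # MPa-1, negative
    b: float  # MPa, P50
    source_points: tuple = ()
    fit_residual: float = 0.0

    def __post_init__(self) -> None:
        if self.a >= 0:
            raise DomainError("slope parameter a must be negative")

    @property
    def p50(self) -> float:
        return self.b

    def __call__(self, psi):
        return sigmoid_percent_embolism(psi, self.a, self.b)


def sigmoid_percent_embolism(psi, a: float, b: float):
    """Percent embolism at water potential psi: 100 - 100/(1 + e^{a(psi-b)})."""
    psi = np.asarray(psi, dtype=float)
    out = 100.0 - 100.0 / (1.0 + np.exp(a * (psi - b)))
    return out if out.ndim else float(out)


def slope_from_point(b: float, psi: float, percent: float) -> float:
    """Solve the sigmoid's slope ``a`` from one (psi, percent) point and P50.

    Inverts ``percent = 100 - 100/(1 + e^{a(psi-b)})``; percent must lie
    strictly inside (0, 100) and psi must differ from b.
    """
    if not (0.0 < percent < 100.0):
        raise DomainError("percent must be strictly inside (0, 100)")
    if psi == b:
        raise DomainError("psi == b pins percent at 50; slope unidentified")
    return float(np.log(100.0 / (100.0 - percent) - 1.0) / (psi - b))


# ---------------------------------------------------------------------------
# image processing


def difference_images(
    stack: ImageStack,
    normalize: Literal["range", "mean", "none"] = "range",
) -> ImageStack:
    """Absolute consecutive-frame differences: N frames in, N-1 out.

    Frames are first brought onto a common intensity scale: ``"range"``
    (default) rescales by the dtype grey range, ``"mean"`` additionally
    rescales each frame to the stack-mean intensity (compensates
    illumination drift), ``"none"`` uses raw grey levels.  Output frame i is
    |frame(i+1) - frame(i)| and carries frame i+1's timestamp (the moment
    the change is first visible).
    """
    frames = stack.frames.astype(float)
    if normalize in ("range", "mean"):
        if np.issubdtype(stack.frames.dtype, np.integer):
            grey_max = float(np.iinfo(stack.frames.dtype).max)
        else:
            grey_max = max(float(frames.max()), 1.0)
        frames = frames / grey_max
    if normalize == "mean":
        target = frames.mean()
        means = frames.mean(axis=(1, 2))
        means = np.where(means == 0, 1.0, means)
        frames = frames * (target / means)[:, None, None]
    diffs = np.abs(np.diff(frames, axis=0))
    return ImageStack(
        frames=diffs,
        timestamps=stack.timestamps[1:],
        sample_id=stack.sample_id,
    )


def default_intensity_threshold(
    diff_stack: ImageStack, n_reference_frames: int = 10, n_sd: float = 5.0
) -> float:
    """Noise-adaptive event threshold: mean + n_sd * sd of early frames."""
    ref = diff_stack.frames[:n_reference_frames]
    return float(ref.mean() + n_sd * ref.std())


def detect_embolism_events(
    diff_stack: ImageStack,
    intensity_threshold: float | None = None,
    min_cluster_px: int = DEFAULT_MIN_CLUSTER_PX,
) -> EmbolismEventMap:
    """Threshold difference frames and count embolism events.

    Pixels above ``intensity_threshold`` are grouped by 8-connectivity;
    clusters smaller than ``min_cluster_px`` are discarded as noise, and a
    pixel already embolized in an earlier frame is never re-counted.  When
    ``intensity_threshold`` is None a noise-adaptive default
    (mean + 5 sd of the first 10 difference frames) is used.
    """
    frames = diff_stack.frames
    if intensity_threshold is None:
        intensity_threshold = default_intensity_threshold(diff_stack)
    grey_upper = max(1.0, float(frames.max()) if frames.size else 1.0)
    if intensity_threshold < 0 or intensity_threshold > grey_upper:
        raise InvalidConfigError("intensity threshold outside grey range")
    if min_cluster_px < 1:
        raise InvalidConfigError("min_cluster_px must be >= 1")

    already = np.zeros(frames.shape[1:], dtype=bool)
    masks = np.zeros_like(frames, dtype=bool)
    n_events = np.zeros(frames.shape[0], dtype=int)
    for i, frame in enumerate(frames):
        above = (frame > intensity_threshold) & ~already
        if not above.any():
            continue
        labels, n_lab = ndimage.label(above, structure=_STRUCTURE_8)
        if n_lab == 0:
            continue
        sizes = np.bincount(labels.ravel())[1:]
        keep = np.flatnonzero(sizes >= min_cluster_px) + 1
        if keep.size == 0:
            continue
        mask = np.isin(labels, keep)
        masks[i] = mask
        already |= mask
        n_events[i] = keep.size
    return EmbolismEventMap(
        masks=masks,
        timestamps=diff_stack.timestamps,
        n_events_per_frame=n_events,
    )


def cumulative_embolism(events: EmbolismEventMap) -> pd.Series:
    """Time-resolved cumulative percent of total embolized pixels.

    Non-decreasing; the final value is 100 by construction.
    """
    counts = events.counts
    total = counts.sum()
    if total == 0:
        raise DomainError("no embolized pixels: percent embolism undefined")
    pct = np.cumsum(counts) / total * 100.0
    return pd.Series(pct, index=events.timestamps, name="percent_embolism")


def psi_at_time(timeline: PsiTimeline, t) -> float:
    """Linearly interpolate the water potential at timestamp ``t``.

    Raises :class:`ExtrapolationError` outside the timeline span — no silent
    extrapolation.
    """
    t = pd.Timestamp(t)
    ts = timeline.timestamps
    if t < ts[0] or t > ts[-1]:
        raise ExtrapolationError(
            f"{t} outside timeline span [{ts[0]}, {ts[-1]}]"
        )
    seconds = (ts.asi8 - ts.asi8[0]) / 1e9
    return float(np.interp((t - ts[0]).total_seconds(), seconds, timeline.psi))


def curve_points(
    cumulative: pd.Series, timeline: PsiTimeline
) -> list[tuple[float, float]]:
    """Pair each cumulative-embolism observation with its interpolated psi."""
    pts = []
    for t, pct in cumulative.items():
        try:
            pts.append((psi_at_time(timeline, t), float(pct)))
        except ExtrapolationError:
            continue
    return pts


# ---------------------------------------------------------------------------
# fitting and derived metrics


def _initial_b(psi: np.ndarray, pct: np.ndarray) -> float:
    """Psi at the 50% crossing by linear interpolation (fit start value)."""
    order = np.argsort(pct)
    p_sorted, psi_sorted = pct[order], psi[order]
    if pct.min() <= 50.0 <= pct.max():
        return float(np.interp(50.0, p_sorted, psi_sorted))
    return float(np.median(psi))


def fit_vulnerability_curve(
    points: Sequence[tuple[float, float]],
    n_restarts: int = 5,
    seed: int = 0,
) -> VulnerabilityCurve:
    """Nonlinear least squares of the embolism sigmoid to (psi, percent) pairs.

    Requires >= 5 points spanning more than 20 percentage points of
    embolism.  ``b`` starts at the interpolated 50% crossing and ``a`` at
    -1, with jittered restarts before declaring non-convergence.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 5:
        raise DegenerateFitError("need >= 5 (psi, percent) points")
    psi, pct = arr[:, 0], arr[:, 1]
    if np.ptp(pct) <= 20.0:
        raise DegenerateFitError(
            "points span <= 20 percentage points of embolism; fit degenerate"
        )

    def resid(theta):
        return sigmoid_percent_embolism(psi, theta[0], theta[1]) - pct

    rng = np.random.default_rng(seed)
    b0 = _initial_b(psi, pct)
    starts = [(-1.0, b0)]
    for _ in range(n_restarts):
        starts.append(
            (-np.exp(rng.normal(0.0, 1.0)), b0 + rng.normal(0.0, 0.5))
        )
    best = None
    for a0, b_start in starts:
        try:
            sol = optimize.least_squares(
                resid,
                x0=[a0, b_start],
                bounds=([-np.inf, -np.inf], [-1e-9, 0.0]),
                method="trf",
            )
        except ValueError:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError(
            f"sigmoid fit failed after {n_restarts + 1} starts "
            f"(n={len(psi)}, percent span={np.ptp(pct):.1f})"
        )
    a_hat, b_hat = best.x
    return VulnerabilityCurve(
        a=float(a_hat),
        b=float(b_hat),
        source_points=tuple(map(tuple, arr)),
        fit_residual=float(2.0 * best.cost),
    )


def species_curve(
    curves: Sequence[VulnerabilityCurve],
    pooling: Literal["mean-params", "pooled-fit"] = "mean-params",
) -> VulnerabilityCurve:
    """Combine per-sample curves into a species curve.

    ``"mean-params"`` (default) averages (a, b) across samples;
    ``"pooled-fit"`` refits the sigmoid to all source points pooled.
    """
    if not curves:
        raise InvalidConfigError("no curves to combine")
    if pooling == "mean-params":
        return VulnerabilityCurve(
            a=float(np.mean([c.a for c in curves])),
            b=float(np.mean([c.b for c in curves])),
            source_points=tuple(p for c in curves for p in c.source_points),
        )
    if pooling == "pooled-fit":
        pts = [p for c in curves for p in c.source_points]
        return fit_vulnerability_curve(pts)
    raise InvalidConfigError(f"unknown pooling {pooling!r}")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (matches printed one-decimal reporting)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(
        decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


def predicted_loss(
    curve: VulnerabilityCurve, psi_min: float, rounded: bool = True
) -> float:
    """Predicted in-situ percent loss of xylem function at psi_min (MPa).

    The vulnerability sigmoid evaluated at the seasonal minimum water
    potential, reported to one decimal (half-up) unless ``rounded=False``.
    """
    if psi_min > 0:
        raise DomainError("psi_min must be <= 0 MPa")
    raw = sigmoid_percent_embolism(psi_min, curve.a, curve.b)
    return round_half_up(raw, 1) if rounded else raw


def safety_margin(psi_min: float, p50: float) -> float:
    """Hydraulic safety margin (MPa): psi_min - P50.

    Positive when the minimum experienced water potential is less negative
    than P50.
    """
    if psi_min > 0 or p50 > 0:
        raise DomainError("psi_min and p50 must be <= 0 MPa")
    return psi_min - p50
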