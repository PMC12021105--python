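"""Downstream analyses on phasor images.

Two-endmember unmixing exploits the linearity of the phasor transform:
the phasor of a mixture lies on the straight segment between the
component phasors, at a position set by the components' in-window
intensity shares.  Projecting a measured point onto the segment
therefore yields the intensity fraction directly; an optional
brightness pair converts it into a number fraction.

The time-series pipeline for reflectance monitoring (e.g. leaf water
uptake) follows the measurement recipe: a per-pixel reference phasor is
averaged over an initial dry period, the Euclidean phasor displacement
from that reference is tracked per frame, a least-squares slope of the
displacement over a trailing time window gives the per-pixel rate of
change, and all rates are normalized by the 99th percentile of the
pooled slope distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .camera import IntensityImage
from .phasor import PhasorImage, PhasorPoint

__all__ = [
    "EndmemberPair",
    "UnmixResult",
    "RateMaps",
    "unmix_two",
    "median_filter2d",
    "background_subtract",
    "reference_phasor",
    "phasor_displacement",
    "rate_of_change",
    "normalize_rates",
]


@dataclass(frozen=True)
class EndmemberPair:
    """Two pure-component phasor positions for linear unmixing.

    ``brightness_a``/``brightness_b`` are relative in-window intensities
    per unit amount of each component (default equal), used to convert
    intensity fractions into number fractions.
    """

    phasor_a: PhasorPoint
    phasor_b: PhasorPoint
    brightness_a: float = 1.0
    brightness_b: float = 1.0

    def __post_init__(self) -> None:
        if self.phasor_a.distance(self.phasor_b) <= 1e-6:
            raise ValueError("endmembers must be distinct (separation > 1e-6)")
        if self.brightness_a <= 0 or self.brightness_b <= 0:
            raise ValueError("brightnesses must be positive")


@dataclass(frozen=True)
class UnmixResult:
    """Fractions of endmember b plus off-segment residual distance."""

    intensity_fraction: np.ndarray | float
    number_fraction: np.ndarray | float
    residual: np.ndarray | float


def _unmix_points(g, s, pair: EndmemberPair):
    a = np.array([pair.phasor_a.g, pair.phasor_a.s])
    b = np.array([pair.phasor_b.g, pair.phasor_b.s])
    ab = b - a
    denom = float(ab @ ab)
    t = ((g - a[0]) * ab[0] + (s - a[1]) * ab[1]) / denom
    t = np.clip(t, 0.0, 1.0)
    proj_g = a[0] + t * ab[0]
    proj_s = a[1] + t * ab[1]
    residual = np.hypot(g - proj_g, s - proj_s)
    # intensity share t of b  ->  number fraction via per-amount brightness
    num = t / pair.brightness_b
    frac_n = num / (num + (1.0 - t) / pair.brightness_a)
    return t, frac_n, residual


def unmix_two(phasor: PhasorPoint | PhasorImage, pair: EndmemberPair) -> UnmixResult:
    """Fraction of endmember b by orthogonal projection onto the segment a-b.

    For a :class:`PhasorPoint` the result fields are floats; for a
    :class:`PhasorImage` they are arrays with NaN at invalid pixels.
    The intensity fraction is clamped to [0, 1]; the distance from the
    point to the segment is reported as a quality metric.
    """
    if isinstance(phasor, PhasorPoint):
        t, fn, res = _unmix_points(phasor.g, phasor.s, pair)
        return UnmixResult(float(t), float(fn), float(res))
    t, fn, res = _unmix_points(phasor.g, phasor.s, pair)
    bad = ~phasor.valid
    for arr in (t, fn, res):
        arr[bad] = np.nan
    return UnmixResult(t, fn, res)


def median_filter2d(image, window: tuple[int, int] = (3, 3)):
    """2-D median filter with edge replication (the standard despeckling
    step; (3,3) for solution images, (9,9) for inhomogeneous samples)."""
    if len(window) != 2 or any(w < 1 or w % 2 == 0 for w in window):
        raise ValueError("window must be a pair of odd positive integers")
    data = np.asarray(getattr(image, "data", image), dtype=float)
    out = ndimage.median_filter(data, size=window, mode="nearest")
    if isinstance(image, IntensityImage):
        return IntensityImage(out, exposure=image.exposure,
                              meta={**image.meta, "median_window": tuple(window)})
    return out


def background_subtract(frames: dict, background: dict) -> dict:
    """Subtract per-filter background frames, clamping at zero.

    Subtraction happens on the raw frames, before the phasor division;
    the order matters and is part of the measurement definition.
    """
    out = {}
    for kind, frame in frames.items():
        if kind not in background:
            raise ValueError(f"missing background frame for {kind!r}")
        data = np.asarray(getattr(frame, "data", frame), dtype=float)
        bg = np.asarray(getattr(background[kind], "data", background[kind]),
                        dtype=float)
        if data.shape != bg.shape:
            raise ValueError("background shape mismatch")
        sub = np.clip(data - bg, 0.0, None)
        if isinstance(frame, IntensityImage):
            out[kind] = IntensityImage(sub, exposure=frame.exposure,
                                       meta={**frame.meta, "background": True})
        else:
            out[kind] = sub
    return out


def reference_phasor(
    series: Sequence[tuple[float, PhasorImage]],
    t_ref: float = 300.0,
) -> PhasorImage:
    """Per-pixel mean phasor over the initial reference period.

    Averages frames with timestamps within ``t_ref`` of the first frame
    (inclusive; default 5 min, the dry-state reference window).  Pixels
    invalid in more than half of the reference frames are invalid
    throughout.
    """
    if not series:
        raise ValueError("empty series")
    times = np.array([t for t, _ in series])
    if times[-1] - times[0] < t_ref:
        raise ValueError("series shorter than the reference period")
    ref_frames = [ph for t, ph in series if t - times[0] <= t_ref]
    shape = ref_frames[0].g.shape
    g_sum = np.zeros(shape)
    s_sum = np.zeros(shape)
    n_valid = np.zeros(shape, dtype=int)
    for ph in ref_frames:
        g_sum += np.where(ph.valid, ph.g, 0.0)
        s_sum += np.where(ph.valid, ph.s, 0.0)
        n_valid += ph.valid
    valid = n_valid > 0.5 * len(ref_frames)
    g0 = np.where(valid, g_sum / np.maximum(n_valid, 1), 0.0)
    s0 = np.where(valid, s_sum / np.maximum(n_valid, 1), 0.0)
    return PhasorImage(g0, s0, valid, {"n_reference_frames": len(ref_frames)})


def phasor_displacement(
    series: Sequence[tuple[float, PhasorImage]],
    reference: PhasorImage,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Euclidean phasor distance from the reference, per pixel and frame.

    Returns (times, displacement, valid) with displacement of shape
    (n_frames, ny, nx); a pixel is valid where both the reference and
    the frame are valid.
    """
    times = np.array([t for t, _ in series], dtype=float)
    disp = np.empty((len(series),) + reference.g.shape)
    valid = np.empty(disp.shape, dtype=bool)
    for i, (_, ph) in enumerate(series):
        disp[i] = np.hypot(ph.g - reference.g, ph.s - reference.s)
        valid[i] = ph.valid & reference.valid
    return times, disp, valid


@dataclass(frozen=True)
class RateMaps:
    """Per-pixel displacement slopes over trailing windows.

    ``slope`` is in phasor-distance units per second; ``normalized`` is
    slope divided by the pooled-percentile constant (set by
    :func:`normalize_rates`, NaN-filled until then).
    """

    times: np.ndarray
    slope: np.ndarray
    valid: np.ndarray
    window: float
    normalization: float | None = None

    @property
    def normalized(self) -> np.ndarray:
        if self.normalization is None:
            return np.full_like(self.slope, np.nan)
        return self.slope / self.normalization


def rate_of_change(
    times: np.ndarray,
    displacement: np.ndarray,
    valid: np.ndarray | None = None,
    window: float = 600.0,
    min_frames: int = 3,
) -> RateMaps:
    """Ordinary least-squares slope of displacement over trailing windows.

    For each frame time t with at least ``window`` seconds of history,
    the per-pixel slope is fitted over frames in (t - window, t].
    Negative slopes are permitted.  Invariant to a global time shift.
    """
    times = np.asarray(times, dtype=float)
    displacement = np.asarray(displacement, dtype=float)
    if valid is None:
        valid = np.ones(displacement.shape, dtype=bool)
    out_idx = [i for i in range(len(times)) if times[i] - times[0] >= window]
    if not out_idx:
        raise ValueError("series shorter than the regression window")
    slopes = np.empty((len(out_idx),) + displacement.shape[1:])
    out_valid = np.empty(slopes.shape, dtype=bool)
    for j, i in enumerate(out_idx):
        sel = (times > times[i] - window) & (times <= times[i])
        if sel.sum() < min_frames:
            raise ValueError(f"window at t={times[i]} holds fewer than "
                             f"{min_frames} frames")
        t = times[sel]
        d = displacement[sel]
        t_c = t - t.mean()
        denom = float(t_c @ t_c)
        slopes[j] = np.tensordot(t_c, d, axes=(0, 0)) / denom
        out_valid[j] = valid[sel].all(axis=0)
    return RateMaps(times[out_idx], slopes, out_valid, window)


def normalize_rates(rates: RateMaps, percentile: float = 99.0) -> RateMaps:
    """Normalize all slopes by the pooled cumulative-histogram percentile.

    The constant is the ``percentile``-th percentile (linear
    interpolation between order statistics) of valid slopes pooled over
    all frames and pixels; it must be positive.
    """
    pool = rates.slope[rates.valid]
    if pool.size == 0:
        raise ValueError("no valid slopes to normalize")
    constant = float(np.percentile(pool, percentile))
    if constant <= 0:
        raise ValueError("normalization constant must be positive")
    return RateMaps(rates.times, rates.slope, rates.valid, rates.window,
                    normalization=constant)
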