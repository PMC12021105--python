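"""Forward model of the tunable polarization filter stack.

A variable retarder sandwiched between two parallel linear polarizers,
both oriented at 45 deg to the retarder's fast axis, transmits

    T(R, lambda) = (1 + cos(2 pi R / lambda)) / 2

where ``R = d * delta_n(lambda)`` is the retardance (optical path
difference between fast and slow axis, in nm).  By tuning R the
transmission approximates a sine- or cosine-shaped spectral filter over
a chosen window, which is the optical front end of the three-frame
spectral-phasor acquisition.  Setting R = 0 gives unit transmission
everywhere (the "total" frame used for normalization).

Because T oscillates in 1/lambda rather than lambda, the match to an
ideal sine/cosine in lambda is only approximate; the fit improves as the
window narrows relative to its center wavelength.  ``calibrate_retardance``
finds the retardance (and sign: a negated sine/cosine may fit best) that
maximizes the Pearson correlation with the ideal target, mirroring how a
measured transmission stack would be calibrated against perfect
sine/cosine templates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "DETECTION_RANGE",
    "SpectralWindow",
    "RetarderModel",
    "TransmissionCurve",
    "FilterSetting",
    "transmission",
    "jones_transmission",
    "ideal_filter_curve",
    "calibrate_retardance",
    "calibrate_filter_bank",
    "realized_curve",
    "retardance_lookup",
]

#: Supported detection range of the InGaAs band considered here (nm).
DETECTION_RANGE = (900.0, 1600.0)

FilterKind = Literal["sine", "cosine", "total"]


@dataclass(frozen=True)
class SpectralWindow:
    """Spectral window [lambda_min, lambda_max] in nm onto which one
    full sine/cosine period (per order) is mapped."""

    lambda_min: float
    lambda_max: float

    def __post_init__(self) -> None:
        if not self.lambda_max > self.lambda_min:
            raise ValueError("lambda_max must exceed lambda_min")
        lo, hi = DETECTION_RANGE
        if self.lambda_min < lo or self.lambda_max > hi:
            raise ValueError(
                f"window [{self.lambda_min}, {self.lambda_max}] nm outside "
                f"supported detection range {DETECTION_RANGE}"
            )

    @property
    def width(self) -> float:
        return self.lambda_max - self.lambda_min

    @property
    def center(self) -> float:
        return 0.5 * (self.lambda_min + self.lambda_max)

    def phase(self, wavelengths, order: int = 1):
        """Window phase x(lambda) = order * 2 pi (lambda - lambda_min) / width.

        The cosine target starts at +1 at ``lambda_min`` and completes
        ``order`` full turns across the window.
        """
        lam = np.asarray(wavelengths, dtype=float)
        return order * 2.0 * np.pi * (lam - self.lambda_min) / self.width

    def grid(self, step: float = 1.0) -> np.ndarray:
        """Wavelength grid with ``step`` nm spacing, inclusive of both ends."""
        n = int(round(self.width / step))
        return np.linspace(self.lambda_min, self.lambda_max, n + 1)


@dataclass(frozen=True)
class RetarderModel:
    """Variable retarder with retardance R = d * delta_n(lambda).

    ``max_retardance`` is the device's retardance ceiling in nm (e.g.
    10400 nm for a typical NIR liquid-crystal variable retarder); pass
    ``None`` for an idealized unbounded device.  ``dispersion`` is an
    optional relative birefringence curve delta_n(lambda)/delta_n(ref),
    defaulting to a constant so the retardance is wavelength independent.
    """

    max_retardance: float | None = 10400.0
    thickness: float | None = None
    dispersion: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.max_retardance is not None and self.max_retardance < 0:
            raise ValueError("max_retardance must be non-negative")

    def effective_retardance(self, retardance: float, wavelengths) -> np.ndarray:
        lam = np.asarray(wavelengths, dtype=float)
        if self.dispersion is None:
            return np.full_like(lam, float(retardance))
        r = float(retardance) * np.asarray(self.dispersion(lam), dtype=float)
        if np.any(r < 0):
            raise ValueError("retardance must stay non-negative at all wavelengths")
        return r

    def search_ceiling(self, window: SpectralWindow, order: int) -> float:
        if self.max_retardance is not None:
            return self.max_retardance
        # Slope matching 2 pi R / lambda_c^2 = order * 2 pi / width gives
        # R ~ order * lambda_c^2 / width; double it for a safe search bound.
        return 2.0 * order * window.center**2 / window.width


@dataclass(frozen=True)
class TransmissionCurve:
    """Sampled transmission fraction on a wavelength grid."""

    wavelengths: np.ndarray
    transmission: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelengths, dtype=float)
        t = np.asarray(self.transmission, dtype=float)
        if lam.shape != t.shape or lam.ndim != 1:
            raise ValueError("wavelengths and transmission must be matching 1-D arrays")
        if np.any(np.diff(lam) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(t < -1e-12) or np.any(t > 1 + 1e-12):
            raise ValueError("transmission values must lie in [0, 1]")
        object.__setattr__(self, "wavelengths", lam)
        object.__setattr__(self, "transmission", np.clip(t, 0.0, 1.0))

    def __call__(self, wavelengths) -> np.ndarray:
        """Linear interpolation; zero outside the sampled support."""
        lam = np.asarray(wavelengths, dtype=float)
        return np.interp(lam, self.wavelengths, self.transmission, left=0.0, right=0.0)


@dataclass(frozen=True)
class FilterSetting:
    """A calibrated retardance approximating one of the three filters.

    ``sign`` records whether the negated sine/cosine fit best; it is
    applied downstream in the phasor transform.  ``fit_r2`` is the
    squared Pearson correlation of the realized transmission with the
    ideal target (``None`` flags a degenerate calibration, e.g. a
    retarder with zero range).
    """

    kind: FilterKind
    retardance: float
    sign: int
    window: SpectralWindow
    order: int = 1
    fit_r2: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "total" and (self.retardance != 0.0 or self.sign != 1):
            raise ValueError("total filter requires retardance 0 and sign +1")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")
        if self.order < 1:
            raise ValueError("order must be a positive integer")
        if self.fit_r2 is not None and not (0.0 <= self.fit_r2 <= 1.0 + 1e-12):
            raise ValueError("fit_r2 must lie in [0, 1]")

    @property
    def degenerate(self) -> bool:
        return self.kind != "total" and self.fit_r2 is None

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "retardance_nm": self.retardance,
            "sign": self.sign,
            "order": self.order,
            "r2": self.fit_r2,
            "lambda_min": self.window.lambda_min,
            "lambda_max": self.window.lambda_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FilterSetting":
        return cls(
            kind=d["kind"],
            retardance=float(d["retardance_nm"]),
            sign=int(d["sign"]),
            order=int(d.get("order", 1)),
            fit_r2=d.get("r2"),
            window=SpectralWindow(float(d["lambda_min"]), float(d["lambda_max"])),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FilterSetting":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def transmission(retardance, wavelength):
    """Transmission of the polarizer-retarder-polarizer stack.

    T(R, lambda) = (1 + cos(2 pi R / lambda)) / 2, relative to the light
    intensity after the first polarizer.  Vectorized over both arguments.
    """
    r = np.asarray(retardance, dtype=float)
    lam = np.asarray(wavelength, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be positive")
    if np.any(r < 0):
        raise ValueError("retardance must be non-negative")
    out = 0.5 * (1.0 + np.cos(2.0 * np.pi * r / lam))
    if out.ndim == 0:
        return float(out)
    return out


def _rotation(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


def jones_transmission(
    polarizer_angles: tuple[float, float],
    retarder_fast_axis: float,
    retardance,
    wavelength,
):
    """General Jones-matrix transmission for polarizer -> retarder -> polarizer.

    Angles in degrees with respect to a common laboratory axis.  The input
    is unpolarized; as in :func:`transmission` the returned fraction is
    referenced to the intensity passed by the first polarizer, so with
    both polarizers parallel at 45 deg to the fast axis this reduces
    exactly to the closed-form T(R, lambda).
    """
    r = np.atleast_1d(np.asarray(retardance, dtype=float))
    lam = np.atleast_1d(np.asarray(wavelength, dtype=float))
    if np.any(lam <= 0):
        raise ValueError("wavelength must be positive")
    r, lam = np.broadcast_arrays(r, lam)

    th1, th2 = (math.radians(a) for a in polarizer_angles)
    phi = math.radians(retarder_fast_axis)
    v_in = np.array([math.cos(th1), math.sin(th1)])  # field after first polarizer
    p2_axis = np.array([math.cos(th2), math.sin(th2)])
    rot, rot_inv = _rotation(phi), _rotation(-phi)

    delta = 2.0 * np.pi * r / lam
    out = np.empty(r.shape, dtype=float)
    for i, d in np.ndenumerate(delta):
        j_ret = rot @ np.diag([1.0, np.exp(1j * d)]) @ rot_inv
        amp = p2_axis @ (j_ret @ v_in)
        out[i] = float(np.abs(amp) ** 2)
    if out.size == 1:
        return float(out.reshape(-1)[0])
    return out


def ideal_filter_curve(
    window: SpectralWindow,
    kind: FilterKind,
    sign: int = 1,
    order: int = 1,
    grid: np.ndarray | None = None,
) -> TransmissionCurve:
    """Ideal sine/cosine/total transmission target over the window.

    cosine: (1 + sign*cos(order * x)) / 2 with x = 2 pi (lambda - lambda_min)/width,
    sine analogous; total is unity everywhere.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if sign not in (-1, 1):
        raise ValueError("sign must be +1 or -1")
    lam = window.grid() if grid is None else np.asarray(grid, dtype=float)
    if kind == "total":
        return TransmissionCurve(lam, np.ones_like(lam))
    x = window.phase(lam, order=order)
    f = np.cos(x) if kind == "cosine" else np.sin(x)
    return TransmissionCurve(lam, 0.5 * (1.0 + sign * f))


def realized_curve(
    setting: FilterSetting,
    retarder: RetarderModel | None = None,
    grid: np.ndarray | None = None,
) -> TransmissionCurve:
    """Physical transmission curve realized by a calibrated setting."""
    lam = setting.window.grid() if grid is None else np.asarray(grid, dtype=float)
    retarder = retarder or RetarderModel(max_retardance=None)
    r = retarder.effective_retardance(setting.retardance, lam)
    return TransmissionCurve(lam, transmission(r, lam))


def _pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def calibrate_retardance(
    window: SpectralWindow,
    kind: Literal["sine", "cosine"],
    retarder: RetarderModel,
    order: int = 1,
    grid_step: float = 1.0,
    search_step: float = 5.0,
) -> FilterSetting:
    """Find the retardance best approximating an ideal sine/cosine target.

    Grid-searches R in [0, max_retardance] in ``search_step`` nm steps,
    scoring each candidate by the Pearson correlation between the realized
    transmission and the ideal target on the window grid; both the positive
    and the negated target are evaluated (the sign of the best correlation
    becomes the setting's sign).  A bounded golden-section refinement
    around the best grid point reproduces a dense scan deterministically.
    Ties break toward the smallest R.
    """
    if kind not in ("sine", "cosine"):
        raise ValueError("calibration targets are 'sine' or 'cosine'")
    lam = window.grid(grid_step)
    if lam.size < 3:
        raise ValueError("degenerate window: fewer than 3 grid points")
    ceiling = retarder.search_ceiling(window, order)
    if ceiling == 0.0:
        # Zero-range device can only realize the total filter.
        return FilterSetting(kind=kind, retardance=0.0, sign=1, window=window,
                             order=order, fit_r2=None)

    target = ideal_filter_curve(window, kind, sign=1, order=order, grid=lam).transmission

    def score(r_val: float) -> float:
        t = transmission(retarder.effective_retardance(r_val, lam), lam)
        r = _pearson_r(t, target)
        return 0.0 if math.isnan(r) else r

    candidates = np.arange(0.0, ceiling + 0.5 * search_step, search_step)
    candidates = np.minimum(candidates, ceiling)
    best_r2, best_idx = -1.0, 0
    scores = [score(r) for r in candidates]
    for i, r in enumerate(scores):
        if r * r > best_r2 + 1e-15:  # strict improvement: ties keep smaller R
            best_r2, best_idx = r * r, i

    lo = max(0.0, candidates[best_idx] - search_step)
    hi = min(ceiling, candidates[best_idx] + search_step)
    res = optimize.minimize_scalar(
        lambda r_val: -score(r_val) ** 2, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-4},
    )
    r_best = float(res.x)
    if score(r_best) ** 2 <= best_r2:  # keep the grid point on non-improvement
        r_best = float(candidates[best_idx])
    r_final = score(r_best)
    return FilterSetting(
        kind=kind,
        retardance=r_best,
        sign=1 if r_final >= 0 else -1,
        window=window,
        order=order,
        fit_r2=float(r_final**2),
    )


def calibrate_filter_bank(
    window: SpectralWindow,
    retarder: RetarderModel | None = None,
    order: int = 1,
    grid_step: float = 1.0,
) -> dict[str, FilterSetting]:
    """Calibrate the sine and cosine settings and add the total filter."""
    retarder = retarder or RetarderModel()
    return {
        "sine": calibrate_retardance(window, "sine", retarder, order=order,
                                     grid_step=grid_step),
        "cosine": calibrate_retardance(window, "cosine", retarder, order=order,
                                       grid_step=grid_step),
        "total": FilterSetting(kind="total", retardance=0.0, sign=1,
                               window=window, order=order, fit_r2=1.0),
    }


def retardance_lookup(
    voltage_table: Sequence[tuple[float, float]], voltage: float
) -> float:
    """Monotone interpolation of a measured voltage -> retardance table.

    The table must be strictly monotone in voltage; retardance of liquid
    crystal devices decreases with drive voltage, so a decreasing second
    column is typical.  Queries outside the table range raise (no
    extrapolation).  Exact at table knots.
    """
    table = sorted((float(v), float(r)) for v, r in voltage_table)
    if len(table) < 2:
        raise ValueError("lookup table needs at least two knots")
    volts = np.array([v for v, _ in table])
    rets = np.array([r for _, r in table])
    if np.any(np.diff(volts) <= 0):
        raise ValueError("voltage values must be strictly monotone")
    dr = np.diff(rets)
    if not (np.all(dr > 0) or np.all(dr < 0)):
        raise ValueError("retardance values must be strictly monotone in voltage")
    if voltage < volts[0] or voltage > volts[-1]:
        raise ValueError(f"voltage {voltage} V outside table range "
                         f"[{volts[0]}, {volts[-1]}] V")
    from scipy.interpolate import PchipInterpolator

    interp = PchipInterpolator(volts, rets)
    return float(interp(voltage))
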