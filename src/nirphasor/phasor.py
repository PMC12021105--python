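"""The spectral-phasor transform and phasor-space operations.

A spectrum I(lambda) restricted to a window [lambda_min, lambda_max]
maps to a point (G, S) on the unit disk:

    G = int I(lambda) cos(x) dlambda / int I(lambda) dlambda
    S = int I(lambda) sin(x) dlambda / int I(lambda) dlambda

with window phase x(lambda) = 2 pi (lambda - lambda_min) / (lambda_max -
lambda_min).  In the optical implementation the integrals are measured
directly: three camera frames taken through a sine-, a cosine-, and a
total-transmission filter give, per pixel,

    S = 2 I_S / I_total - 1,      G = 2 I_G / I_total - 1,

identical to the Fourier definition when the filters are ideal.
``spectral_phasor`` is the exact-integration oracle against which the
frame-based pipeline is verified.

Because a variable retarder realizes cos(2 pi R / lambda) rather than a
cosine in lambda, realized phasor positions are slightly displaced from
their ideal positions; ``distortion_map`` tabulates the displacement for
narrowband probes and provides an invertible look-up correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import points_in_polygon
from .optics import FilterSetting, SpectralWindow, TransmissionCurve, realized_curve
from .synth import Spectrum

__all__ = [
    "PhasorPoint",
    "PhasorImage",
    "CorrectionField",
    "PhasorCorrection",
    "spectral_phasor",
    "phasor_through_filters",
    "phasor_from_frames",
    "distortion_map",
    "estimate_correction_field",
    "apply_correction",
    "angular_color",
    "polygon_gate",
    "phasor_histogram",
]

#: Pixels whose modulus exceeds 1 by more than this are discarded, as in
#: the practice of ignoring points outside the unity circle.
UNIT_CIRCLE_TOLERANCE = 0.05


@dataclass(frozen=True)
class PhasorPoint:
    g: float
    s: float

    @property
    def modulus(self) -> float:
        return float(np.hypot(self.g, self.s))

    @property
    def phase(self) -> float:
        return float(np.arctan2(self.s, self.g))

    def distance(self, other: "PhasorPoint") -> float:
        return float(np.hypot(self.g - other.g, self.s - other.s))


@dataclass(frozen=True)
class PhasorImage:
    """Per-pixel (G, S) with a validity mask and acquisition provenance."""

    g: np.ndarray
    s: np.ndarray
    valid: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = np.asarray(self.g, dtype=float)
        s = np.asarray(self.s, dtype=float)
        valid = np.asarray(self.valid, dtype=bool)
        if not (g.shape == s.shape == valid.shape):
            raise ValueError("G, S and validity mask must share a shape")
        if np.any(~np.isfinite(g[valid])) or np.any(~np.isfinite(s[valid])):
            raise ValueError("valid pixels must be finite")
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "valid", valid)

    @property
    def modulus(self) -> np.ndarray:
        return np.hypot(self.g, self.s)

    @property
    def phase(self) -> np.ndarray:
        return np.arctan2(self.s, self.g)

    def mean_point(self) -> PhasorPoint:
        if not self.valid.any():
            raise ValueError("no valid pixels")
        return PhasorPoint(float(self.g[self.valid].mean()),
                           float(self.s[self.valid].mean()))

    def spread(self) -> float:
        """Sum of the G and S standard deviations over valid pixels."""
        if not self.valid.any():
            raise ValueError("no valid pixels")
        return float(self.g[self.valid].std() + self.s[self.valid].std())


@dataclass(frozen=True)
class CorrectionField:
    """Additive per-pixel (dG, dS) offsets from a uniform reference."""

    dg: np.ndarray
    ds: np.ndarray

    def __post_init__(self) -> None:
        dg = np.asarray(self.dg, dtype=float)
        ds = np.asarray(self.ds, dtype=float)
        if dg.shape != ds.shape:
            raise ValueError("dG and dS must share a shape")
        if np.any(~np.isfinite(dg)) or np.any(~np.isfinite(ds)):
            raise ValueError("correction field must be finite")
        object.__setattr__(self, "dg", dg)
        object.__setattr__(self, "ds", ds)


def _window_slice(spectrum: Spectrum, window: SpectralWindow):
    lam = spectrum.wavelengths
    sel = (lam >= window.lambda_min) & (lam <= window.lambda_max)
    if sel.sum() < 2:
        raise ValueError("spectrum grid has fewer than 2 points in the window")
    return lam[sel], spectrum.intensity[sel]


def spectral_phasor(spectrum: Spectrum, window: SpectralWindow) -> PhasorPoint:
    """Exact spectral phasor by trapezoid integration over the window."""
    lam, inten = _window_slice(spectrum, window)
    total = np.trapezoid(inten, lam)
    if total <= 0:
        raise ValueError("zero total intensity in the window")
    x = window.phase(lam)
    g = np.trapezoid(inten * np.cos(x), lam) / total
    s = np.trapezoid(inten * np.sin(x), lam) / total
    return PhasorPoint(float(g), float(s))


def phasor_through_filters(
    spectrum: Spectrum,
    curves: tuple[TransmissionCurve, TransmissionCurve, TransmissionCurve],
    signs: tuple[int, int] = (1, 1),
) -> PhasorPoint:
    """Phasor computed through supplied (possibly imperfect) transmissions.

    ``curves`` are the (sine, cosine, total) transmission curves; the
    integrals run over each curve's sampled support on the spectrum's
    grid.  ``signs`` = (sign_s, sign_g) undo negated filter fits.  With
    ideal curves this equals :func:`spectral_phasor` exactly.
    """
    t_sin, t_cos, t_tot = curves
    lam = spectrum.wavelengths
    sel = (lam >= t_tot.wavelengths[0]) & (lam <= t_tot.wavelengths[-1])
    lam_w, inten = lam[sel], spectrum.intensity[sel]
    i_tot = np.trapezoid(inten * t_tot(lam_w), lam_w)
    if i_tot <= 0:
        raise ValueError("zero transmitted intensity through the total filter")
    i_s = np.trapezoid(inten * t_sin(lam_w), lam_w)
    i_g = np.trapezoid(inten * t_cos(lam_w), lam_w)
    s = signs[0] * (2.0 * i_s / i_tot - 1.0)
    g = signs[1] * (2.0 * i_g / i_tot - 1.0)
    return PhasorPoint(float(g), float(s))


def phasor_from_frames(
    i_s,
    i_g,
    i_total,
    signs: tuple[int, int] = (1, 1),
    min_total: float | None = None,
    provenance: dict | None = None,
) -> PhasorImage:
    """Per-pixel phasor from the three filtered camera frames.

    S = sign_s (2 I_S / I_total - 1) and G analogously.  Pixels with
    I_total below ``min_total`` (default max(10 DN, 1% of the image
    maximum)) are marked invalid, as are pixels falling more than
    ``UNIT_CIRCLE_TOLERANCE`` outside the unit circle.  Frames must be
    co-registered and background-subtracted beforehand.
    """
    arr_s = np.asarray(getattr(i_s, "data", i_s), dtype=float)
    arr_g = np.asarray(getattr(i_g, "data", i_g), dtype=float)
    arr_t = np.asarray(getattr(i_total, "data", i_total), dtype=float)
    if not (arr_s.shape == arr_g.shape == arr_t.shape):
        raise ValueError("the three frames must share a shape")
    if min_total is None:
        min_total = max(10.0, 0.01 * float(arr_t.max(initial=0.0)))
    valid = arr_t >= max(min_total, np.finfo(float).tiny)
    denom = np.where(valid, arr_t, 1.0)
    s = signs[0] * (2.0 * arr_s / denom - 1.0)
    g = signs[1] * (2.0 * arr_g / denom - 1.0)
    s[~valid] = 0.0
    g[~valid] = 0.0
    valid &= np.hypot(g, s) <= 1.0 + UNIT_CIRCLE_TOLERANCE
    if not valid.any():
        warnings.warn("all pixels invalid (low signal or outside unit circle)",
                      stacklevel=2)
    prov = dict(provenance or {})
    prov.setdefault("signs", tuple(int(x) for x in signs))
    prov["min_total"] = float(min_total)
    return PhasorImage(g, s, valid, prov)


def distortion_map(
    window: SpectralWindow,
    settings: dict[str, FilterSetting],
    probe_lines: Sequence[float],
    retarder=None,
) -> "PhasorCorrection":
    """Tabulate ideal vs realized phasor positions for narrowband probes.

    For each probe wavelength the ideal position is (cos x0, sin x0); the
    realized position follows from the calibrated filter transmissions
    evaluated at the probe wavelength (the total filter transmits fully).
    Monotone interpolation of the tabulated displacement over realized
    phase yields an invertible look-up correction for narrowband signals.
    """
    probes = np.asarray(sorted(probe_lines), dtype=float)
    if np.any(probes < window.lambda_min) or np.any(probes > window.lambda_max):
        raise ValueError("probe lines must lie inside the window")
    x0 = window.phase(probes)
    ideal = np.column_stack([np.cos(x0), np.sin(x0)])

    curves = {k: realized_curve(settings[k], retarder=retarder,
                                grid=window.grid())
              for k in ("sine", "cosine")}
    t_s = curves["sine"](probes)
    t_c = curves["cosine"](probes)
    realized = np.column_stack([
        settings["cosine"].sign * (2.0 * t_c - 1.0),
        settings["sine"].sign * (2.0 * t_s - 1.0),
    ])
    return PhasorCorrection(probes, ideal, realized)


class PhasorCorrection:
    """Look-up correction from realized to ideal phasor positions.

    Built from a probe-line table; corrects narrowband measurements by
    interpolating the tabulated (ideal - realized) displacement as a
    function of the realized phase angle.  Exact at the table knots.
    """

    def __init__(self, probes: np.ndarray, ideal: np.ndarray, realized: np.ndarray):
        self.probes = probes
        self.ideal = ideal
        self.realized = realized
        self.displacement = np.linalg.norm(ideal - realized, axis=1)
        theta = np.unwrap(np.arctan2(realized[:, 1], realized[:, 0]))
        if np.all(np.diff(theta) < 0):
            theta = theta[::-1]
            self._theta = theta
            self._delta = (ideal - realized)[::-1]
        elif np.all(np.diff(theta) > 0):
            self._theta = theta
            self._delta = ideal - realized
        else:
            raise ValueError("realized phase is not monotone over the probes; "
                             "use a denser probe table or a narrower window")

    def table(self) -> list[tuple[float, PhasorPoint, PhasorPoint, float]]:
        return [
            (float(lam), PhasorPoint(*self.ideal[i]), PhasorPoint(*self.realized[i]),
             float(self.displacement[i]))
            for i, lam in enumerate(self.probes)
        ]

    def _interp_delta(self, theta: np.ndarray) -> np.ndarray:
        base = self._theta[0]
        th = np.mod(theta - base, 2.0 * np.pi) + base
        dg = np.interp(th, self._theta, self._delta[:, 0])
        ds = np.interp(th, self._theta, self._delta[:, 1])
        return np.column_stack([dg, ds])

    def apply(self, point: PhasorPoint) -> PhasorPoint:
        delta = self._interp_delta(np.atleast_1d(point.phase))[0]
        return PhasorPoint(point.g + delta[0], point.s + delta[1])

    def apply_image(self, phasor: PhasorImage) -> PhasorImage:
        delta = self._interp_delta(phasor.phase.ravel()).reshape(
            phasor.g.shape + (2,))
        return PhasorImage(phasor.g + delta[..., 0], phasor.s + delta[..., 1],
                           phasor.valid, {**phasor.provenance, "lut_corrected": True})


def estimate_correction_field(
    reference_stacks: Sequence[PhasorImage],
) -> CorrectionField:
    """Spatial correction field from repeated uniform-reference acquisitions.

    The reference (e.g. a white diffuse reflectance standard) is
    spectrally uniform across the field, so any spatial structure in its
    mean phasor is instrumental (retarder inhomogeneity, illumination).
    Returns additive offsets dG(x,y) = mean_ref G(x,y) - <G>, likewise dS.
    """
    if not reference_stacks:
        raise ValueError("need at least one reference acquisition")
    shape = reference_stacks[0].g.shape
    g_sum = np.zeros(shape)
    s_sum = np.zeros(shape)
    n_valid = np.zeros(shape, dtype=int)
    for ph in reference_stacks:
        if ph.g.shape != shape:
            raise ValueError("reference stacks must share a shape")
        g_sum += np.where(ph.valid, ph.g, 0.0)
        s_sum += np.where(ph.valid, ph.s, 0.0)
        n_valid += ph.valid
    ever = n_valid > 0
    if ever.mean() < 0.5:
        raise ValueError("more than 50% of reference pixels are invalid")
    g_ref = np.where(ever, g_sum / np.maximum(n_valid, 1), 0.0)
    s_ref = np.where(ever, s_sum / np.maximum(n_valid, 1), 0.0)
    dg = np.where(ever, g_ref - g_ref[ever].mean(), 0.0)
    ds = np.where(ever, s_ref - s_ref[ever].mean(), 0.0)
    return CorrectionField(dg, ds)


def apply_correction(phasor: PhasorImage, fieldcorr: CorrectionField) -> PhasorImage:
    if fieldcorr.dg.shape != phasor.g.shape:
        raise ValueError("correction field shape mismatch")
    return PhasorImage(phasor.g - fieldcorr.dg, phasor.s - fieldcorr.ds,
                       phasor.valid,
                       {**phasor.provenance, "spatially_corrected": True})


def angular_color(
    phasor: PhasorImage,
    angle_range: tuple[float, float] = (-np.pi, np.pi),
    n_colors: int = 256,
) -> np.ndarray:
    """Map the phasor phase linearly onto integer color indices.

    Phases are wrapped into ``angle_range`` (a 2 pi interval), so theta =
    +pi and -pi receive the same index.  Invalid pixels get -1.
    """
    lo, hi = angle_range
    if not np.isclose(hi - lo, 2.0 * np.pi):
        raise ValueError("angle_range must span 2 pi")
    theta = np.mod(phasor.phase - lo, 2.0 * np.pi)
    idx = np.floor(theta / (2.0 * np.pi) * n_colors).astype(int)
    idx = np.clip(idx, 0, n_colors - 1)
    idx[~phasor.valid] = -1
    return idx


def polygon_gate(
    phasor: PhasorImage,
    polygons: Sequence[tuple[int, np.ndarray]],
) -> np.ndarray:
    """Label pixels by phasor-space polygon gates.

    ``polygons`` is a list of (label, vertices) with vertices in (G, S);
    containment uses the even-odd rule with boundary points inside.
    Valid pixels matching no gate get 0; invalid pixels get -1.  Later
    gates overwrite earlier ones where they overlap.
    """
    labels = np.zeros(phasor.g.shape, dtype=int)
    pts = np.column_stack([phasor.g.ravel(), phasor.s.ravel()])
    for label, verts in polygons:
        if int(label) <= 0:
            raise ValueError("gate labels must be positive integers")
        inside = points_in_polygon(pts, verts).reshape(phasor.g.shape)
        labels[inside & phasor.valid] = int(label)
    labels[~phasor.valid] = -1
    return labels


def phasor_histogram(
    phasor: PhasorImage,
    bins: int = 64,
    hist_range: tuple[tuple[float, float], tuple[float, float]] = ((-1, 1), (-1, 1)),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D histogram of valid phasor points over (G, S).

    Returns (counts, g_edges, s_edges); counts sum to the number of
    valid pixels inside the range.
    """
    g = phasor.g[phasor.valid]
    s = phasor.s[phasor.valid]
    counts, g_edges, s_edges = np.histogram2d(g, s, bins=bins, range=hist_range)
    return counts, g_edges, s_edges
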