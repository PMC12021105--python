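"""Synthetic spectra, spatial scenes, and reflectance time series.

Generators for the kinds of inputs the imaging method is used on:

* narrow Gaussian monochromator lines (FWHM 15 +/- 2 nm),
* NIR fluorophore emission bands modeled on single-walled carbon
  nanotube (SWCNT) chiralities with peaks between 900 and 1200 nm,
  including a pair of species only 5 nm apart and a defect-shifted
  variant (990 -> 1040 nm with broadening),
* broadband reflectance spectra: two polymers that differ only in the
  1400-1600 nm region, and a leaf whose spectrum is a high scattering
  plateau (900-1350 nm) multiplied by a water absorption band centered
  near 1450 nm whose depth grows with water content.

Spectral shapes are parameterized analytic stand-ins with
figure-plausible defaults, shipped as named fixtures; they are not
digitized measurement curves.  Intensities are spectral photon flux
densities (photons s^-1 cm^-2 nm^-1) so the camera model's flux
equation applies without unit conversion.

All generators are pure functions of their arguments; randomness enters
only downstream in the camera model via an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np

from .geometry import points_in_polygon

__all__ = [
    "DEFAULT_GRID",
    "Spectrum",
    "SpectralCube",
    "Region",
    "SceneSpec",
    "gaussian_line",
    "fluorophore_spectrum",
    "reflectance_spectrum",
    "leaf_water_band",
    "render_scene",
    "water_uptake_series",
    "CHIRALITY_PRESETS",
    "DEFECT_PAIR",
]

#: Default wavelength grid (nm): full detection range at 1 nm spacing.
DEFAULT_GRID = np.arange(900.0, 1600.0 + 0.5, 1.0)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class Spectrum:
    """Spectral photon flux density on a strictly increasing grid."""

    wavelengths: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelengths, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if lam.ndim != 1 or lam.shape != inten.shape:
            raise ValueError("wavelengths and intensity must be matching 1-D arrays")
        if np.any(np.diff(lam) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(inten < 0):
            raise ValueError("intensity must be non-negative")
        object.__setattr__(self, "wavelengths", lam)
        object.__setattr__(self, "intensity", inten)

    @property
    def total_flux(self) -> float:
        """Trapezoid integral over the full grid (photons s^-1 cm^-2)."""
        return float(np.trapezoid(self.intensity, self.wavelengths))

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(self.wavelengths, self.intensity * float(factor))

    def __add__(self, other: "Spectrum") -> "Spectrum":
        if not np.array_equal(self.wavelengths, other.wavelengths):
            raise ValueError("spectra must share a wavelength grid")
        return Spectrum(self.wavelengths, self.intensity + other.intensity)


@dataclass(frozen=True)
class SpectralCube:
    """(y, x, lambda) scene of spectral photon flux densities."""

    data: np.ndarray
    wavelengths: np.ndarray
    pixel_area: float = 9e-6  # cm^2

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        lam = np.asarray(self.wavelengths, dtype=float)
        if data.ndim != 3 or data.shape[2] != lam.size:
            raise ValueError("cube must be (y, x, lambda) matching the grid")
        if np.any(np.diff(lam) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(data < 0):
            raise ValueError("cube values must be non-negative")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "wavelengths", lam)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def pixel_spectrum(self, y: int, x: int) -> Spectrum:
        return Spectrum(self.wavelengths, self.data[y, x])

    def total_flux_image(self) -> np.ndarray:
        return np.trapezoid(self.data, self.wavelengths, axis=2)


def _require_on_grid(center: float, grid: np.ndarray, what: str) -> None:
    if center < grid[0] or center > grid[-1]:
        raise ValueError(f"{what} {center} nm outside grid "
                         f"[{grid[0]}, {grid[-1]}] nm")


def gaussian_line(
    center: float,
    fwhm: float = 15.0,
    total_flux: float = 1.0,
    grid: np.ndarray | None = None,
) -> Spectrum:
    """Gaussian monochromator-like line, trapezoid-normalized to ``total_flux``."""
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    lam = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    _require_on_grid(center, lam, "line center")
    sigma = fwhm * _FWHM_TO_SIGMA
    profile = np.exp(-0.5 * ((lam - center) / sigma) ** 2)
    norm = np.trapezoid(profile, lam)
    if norm == 0:
        raise ValueError("line profile vanishes on the grid")
    return Spectrum(lam, profile * (total_flux / norm))


def fluorophore_spectrum(
    peak: float,
    fwhm: float = 30.0,
    shape: Literal["gaussian", "lorentzian"] = "gaussian",
    total_flux: float = 1.0,
    grid: np.ndarray | None = None,
) -> Spectrum:
    """Emission band of an NIR fluorophore (Gaussian or truncated Lorentzian).

    The Lorentzian is truncated to the grid and renormalized so the
    trapezoid integral equals ``total_flux``.
    """
    lam = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    _require_on_grid(peak, lam, "emission peak")
    if shape == "gaussian":
        return gaussian_line(peak, fwhm, total_flux, lam)
    if shape == "lorentzian":
        gamma = fwhm / 2.0
        profile = gamma**2 / ((lam - peak) ** 2 + gamma**2)
        return Spectrum(lam, profile * (total_flux / np.trapezoid(profile, lam)))
    raise ValueError(f"unknown shape {shape!r}")


# Named emission-band fixtures patterned on five SWCNT chiralities with
# peaks spanning 950-1120 nm; the (9,4)/(8,4)-like pair is deliberately
# 5 nm apart to probe the resolution limit.  Values are fixture choices,
# not measured band positions.
CHIRALITY_PRESETS: dict[str, dict[str, float]] = {
    "(8,3)": {"peak": 952.0, "fwhm": 24.0},
    "(6,5)": {"peak": 985.0, "fwhm": 30.0},
    "(7,5)": {"peak": 1025.0, "fwhm": 28.0},
    "(9,4)": {"peak": 1115.0, "fwhm": 30.0},
    "(8,4)": {"peak": 1120.0, "fwhm": 30.0},
}

#: Pristine vs covalently defect-functionalized emitter: the defect band
#: is red-shifted (990 -> 1040 nm) and broadened.  Fixture values.
DEFECT_PAIR: dict[str, dict[str, float]] = {
    "pristine": {"peak": 990.0, "fwhm": 26.0},
    "defect": {"peak": 1040.0, "fwhm": 36.0},
}


def leaf_water_band(wavelengths, water_fraction: float) -> np.ndarray:
    """Multiplicative water absorption factor centered at 1450 nm.

    exp(-water_fraction * depth * b(lambda)) with a Gaussian band b;
    depth chosen so a fully hydrated leaf loses ~85% reflectance at the
    band center.  Strictly decreasing in ``water_fraction`` at 1450 nm.
    """
    lam = np.asarray(wavelengths, dtype=float)
    band = np.exp(-0.5 * ((lam - 1450.0) / 55.0) ** 2)
    return np.exp(-1.9 * float(water_fraction) * band)


def reflectance_spectrum(
    kind: Literal["polymerA", "polymerB", "leaf"],
    water_fraction: float = 0.0,
    grid: np.ndarray | None = None,
    scale: float = 1.0,
) -> Spectrum:
    """Broadband reflectance stand-ins.

    ``polymerA``/``polymerB`` share an identical smooth plateau below
    1400 nm and differ only through distinct absorption dips in the
    1400-1600 nm overtone region (as for polyethylene vs polyamide).
    ``leaf`` is a high scattering plateau over 900-1350 nm multiplied by
    the 1450 nm water band, whose depth increases with ``water_fraction``.
    ``scale`` converts the dimensionless reflectance into a photon flux
    density for scene rendering.
    """
    lam = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if kind in ("polymerA", "polymerB"):
        plateau = 0.9 - 1e-5 * (lam - 900.0)  # nearly flat, featureless
        if kind == "polymerA":
            dip = 0.45 * np.exp(-0.5 * ((lam - 1540.0) / 35.0) ** 2)
        else:
            dip = (0.35 * np.exp(-0.5 * ((lam - 1460.0) / 20.0) ** 2)
                   + 0.30 * np.exp(-0.5 * ((lam - 1570.0) / 22.0) ** 2))
        refl = plateau * (1.0 - dip)
    elif kind == "leaf":
        if not 0.0 <= water_fraction <= 1.0:
            raise ValueError("water_fraction must lie in [0, 1]")
        # scattering plateau rolls off gently above 1350 nm
        plateau = 0.55 / (1.0 + np.exp((lam - 1520.0) / 90.0)) + 0.25
        refl = plateau * leaf_water_band(lam, water_fraction)
    else:
        raise ValueError(f"unknown reflectance kind {kind!r}")
    return Spectrum(lam, refl * float(scale))


@dataclass(frozen=True)
class Region:
    """A scene region bound to one spectrum.

    ``geometry`` is either ``("disk", (cy, cx), radius)`` or
    ``("polygon", vertices)`` with vertices in (y, x) pixel coordinates.
    ``spectrum`` is the per-pixel spectral flux density at profile
    weight 1 (i.e. at the region's brightest pixel).
    """

    geometry: tuple
    spectrum: Spectrum
    label: int = 1

    def mask_and_weight(
        self, shape: tuple[int, int], profile: str
    ) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = shape
        yy, xx = np.mgrid[0:ny, 0:nx]
        if self.geometry[0] == "disk":
            (cy, cx), radius = self.geometry[1], self.geometry[2]
            if not (0 <= cy < ny and 0 <= cx < nx):
                raise ValueError("disk center outside image bounds")
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            mask = d2 <= radius**2
            if profile == "uniform":
                weight = mask.astype(float)
            elif profile == "gaussian":
                sigma = radius / 2.0
                weight = np.where(mask, np.exp(-0.5 * d2 / sigma**2), 0.0)
            else:
                raise ValueError(f"unknown intensity profile {profile!r}")
        elif self.geometry[0] == "polygon":
            verts = np.asarray(self.geometry[1], dtype=float)
            if (verts[:, 0].min() < 0 or verts[:, 0].max() >= ny
                    or verts[:, 1].min() < 0 or verts[:, 1].max() >= nx):
                raise ValueError("polygon outside image bounds")
            pts = np.column_stack([yy.ravel(), xx.ravel()])
            mask = points_in_polygon(pts, verts).reshape(shape)
            weight = mask.astype(float)  # polygons render uniform
        else:
            raise ValueError(f"unknown geometry {self.geometry[0]!r}")
        return mask, weight


@dataclass(frozen=True)
class SceneSpec:
    shape: tuple[int, int]
    regions: Sequence[Region]
    profile: Literal["uniform", "gaussian"] = "uniform"
    background: Spectrum | None = None
    pixel_area: float = 9e-6


def render_scene(spec: SceneSpec) -> SpectralCube:
    """Deterministically rasterize a scene into a spectral cube.

    Per-pixel spectrum = sum over regions of (region spectrum x profile
    weight) + background.  The total cube flux therefore equals the sum
    over regions of region flux times profile mass (plus background),
    which the tests assert as a conservation property.
    """
    grids = [r.spectrum.wavelengths for r in spec.regions]
    if spec.background is not None:
        grids.append(spec.background.wavelengths)
    if not grids:
        raise ValueError("scene needs at least one region or a background")
    lam = grids[0]
    for g in grids[1:]:
        if not np.array_equal(g, lam):
            raise ValueError("all scene spectra must share a wavelength grid")
    ny, nx = spec.shape
    cube = np.zeros((ny, nx, lam.size))
    if spec.background is not None:
        cube += spec.background.intensity
    for region in spec.regions:
        _, weight = region.mask_and_weight(spec.shape, spec.profile)
        cube += weight[:, :, None] * region.spectrum.intensity
    return SpectralCube(cube, lam, pixel_area=spec.pixel_area)


def label_image(spec: SceneSpec) -> np.ndarray:
    """Ground-truth region labels (later regions overwrite earlier ones)."""
    out = np.zeros(spec.shape, dtype=int)
    for region in spec.regions:
        mask, _ = region.mask_and_weight(spec.shape, spec.profile)
        out[mask] = region.label
    return out


def water_uptake_series(
    shape: tuple[int, int],
    onset: np.ndarray,
    rate: np.ndarray,
    frame_period: float = 5.0,
    duration: float = 600.0,
    illumination: float = 1e11,
    grid: np.ndarray | None = None,
    leaf_mask: np.ndarray | None = None,
) -> Iterator[tuple[float, SpectralCube]]:
    """Leaf reflectance time series with per-pixel water-uptake ramps.

    Each pixel's water fraction follows a clamped linear ramp
    ``clip(rate * (t - onset), 0, 1)``.  Frames are timestamped at the
    acquisition period (default 5 s, i.e. 0.2 hyperspectral cubes per
    second).  ``illumination`` scales the dimensionless leaf reflectance
    into photons s^-1 cm^-2 nm^-1 at the plateau.
    """
    onset = np.broadcast_to(np.asarray(onset, dtype=float), shape)
    rate = np.broadcast_to(np.asarray(rate, dtype=float), shape)
    if np.any(rate < 0):
        raise ValueError("uptake rates must be non-negative")
    lam = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    dry = reflectance_spectrum("leaf", 0.0, grid=lam).intensity
    band = np.exp(-0.5 * ((lam - 1450.0) / 55.0) ** 2)
    if leaf_mask is None:
        leaf_mask = np.ones(shape, dtype=bool)
    n_frames = int(np.floor(duration / frame_period)) + 1
    for k in range(n_frames):
        t = k * frame_period
        w = np.clip(rate * (t - onset), 0.0, 1.0)
        attenuation = np.exp(-1.9 * w[:, :, None] * band[None, None, :])
        cube = illumination * dry[None, None, :] * attenuation
        cube *= leaf_mask[:, :, None]
        yield t, SpectralCube(cube, lam)
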