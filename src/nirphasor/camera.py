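"""EMVA-1288 style camera model and three-frame acquisition simulator.

The detected signal mu_y (in digital numbers, DN) carries a variance
that is a linear function of the signal,

    sigma_y^2 = K^2 (sigma_d^2 + sigma_q^2) + K (mu_y - mu_y_dark),

combining read noise sigma_d^2 (electrons^2), quantization noise
sigma_q^2 (DN^2, 1/12 for an ideal quantizer) and shot noise through
the gain K (DN per photoelectron).  The photon flux incident on a pixel
relates to the signal via

    Phi = mu_y / (K * QE * A * t_exp)    [photons s^-1 cm^-2].

Defaults follow a thermoelectrically cooled InGaAs camera:
K = 1.1e-3 DN/e-, sigma_d^2 = 1000 e-^2, sigma_q^2 = 1/12 DN^2 at
12 bit, QE = 0.56 (near 990 nm), A = 9e-6 cm^2, t_exp = 3 s; the dark
offset defaults to zero since measured frames are background-corrected.

Noise in :func:`acquire_frame` is Gaussian with the variance above (not
compound Poisson): shot noise enters only through the linear signal
term, which is the standard photon-transfer description and lets
Monte-Carlo frame statistics be checked against the closed form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .optics import FilterSetting, TransmissionCurve, realized_curve
from .phasor import PhasorImage
from .synth import SpectralCube

log = logging.getLogger(__name__)

__all__ = [
    "CameraModel",
    "IntensityImage",
    "noise_variance",
    "photon_flux",
    "signal_from_flux",
    "acquire_frame",
    "acquire_three",
    "phasor_spread",
    "predicted_phasor_spread",
]


@dataclass(frozen=True)
class CameraModel:
    """Photon-transfer parameters of the detector."""

    gain: float = 1.1e-3                  # K, DN per electron
    read_noise_var: float = 1000.0        # sigma_d^2, electrons^2
    quantization_var: float = 1.0 / 12.0  # sigma_q^2, DN^2
    quantum_efficiency: float | Callable[[np.ndarray], np.ndarray] = 0.56
    pixel_area: float = 9e-6              # A, cm^2
    exposure: float = 3.0                 # t_exp, s
    bit_depth: int = 12
    dark_offset: float = 0.0              # mu_y_dark, DN

    def __post_init__(self) -> None:
        for name in ("gain", "read_noise_var", "quantization_var",
                     "pixel_area", "exposure", "dark_offset"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.bit_depth < 1:
            raise ValueError("bit_depth must be positive")
        if not callable(self.quantum_efficiency):
            qe = float(self.quantum_efficiency)
            if not 0.0 <= qe <= 1.0:
                raise ValueError("quantum efficiency must lie in [0, 1]")

    @property
    def full_scale(self) -> int:
        return 2**self.bit_depth - 1

    def qe_at(self, wavelengths) -> np.ndarray:
        lam = np.asarray(wavelengths, dtype=float)
        if callable(self.quantum_efficiency):
            qe = np.asarray(self.quantum_efficiency(lam), dtype=float)
            if np.any(qe < 0) or np.any(qe > 1):
                raise ValueError("quantum efficiency curve must lie in [0, 1]")
            return qe
        return np.full_like(lam, float(self.quantum_efficiency))

    def with_exposure(self, exposure: float) -> "CameraModel":
        return replace(self, exposure=exposure)


@dataclass(frozen=True)
class IntensityImage:
    """Single filtered camera frame in DN plus acquisition metadata."""

    data: np.ndarray
    exposure: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "data", np.asarray(self.data, dtype=float))


def noise_variance(signal, camera: CameraModel):
    """Closed-form signal variance sigma_y^2 in DN^2 at mean signal ``signal``."""
    mu = np.asarray(signal, dtype=float)
    if np.any(mu < camera.dark_offset):
        raise ValueError("signal must not fall below the dark offset")
    k = camera.gain
    var = k * k * (camera.read_noise_var + camera.quantization_var) \
        + k * (mu - camera.dark_offset)
    return float(var) if var.ndim == 0 else var


def photon_flux(signal, camera: CameraModel, wavelength_for_qe: float | None = None):
    """Convert a mean signal in DN to photon flux (photons s^-1 cm^-2)."""
    qe = (camera.qe_at(wavelength_for_qe) if wavelength_for_qe is not None
          else camera.qe_at(990.0))
    denom = camera.gain * float(qe) * camera.pixel_area * camera.exposure
    if denom == 0:
        raise ValueError("gain, QE, pixel area and exposure must all be positive")
    mu = np.asarray(signal, dtype=float)
    out = mu / denom
    return float(out) if out.ndim == 0 else out


def signal_from_flux(flux, camera: CameraModel, wavelength_for_qe: float | None = None):
    """Inverse of :func:`photon_flux`: mean signal in DN for a given flux."""
    qe = (camera.qe_at(wavelength_for_qe) if wavelength_for_qe is not None
          else camera.qe_at(990.0))
    phi = np.asarray(flux, dtype=float)
    out = phi * camera.gain * float(qe) * camera.pixel_area * camera.exposure
    return float(out) if out.ndim == 0 else out


def expected_signal(
    cube: SpectralCube,
    filt: FilterSetting | TransmissionCurve,
    camera: CameraModel,
) -> np.ndarray:
    """Noise-free expected signal in DN for each pixel.

    Expected photoelectrons are t_exp * A * integral I(lambda) T(lambda)
    QE(lambda) dlambda over the filter's spectral support; DN adds the
    gain and dark offset.
    """
    if isinstance(filt, FilterSetting):
        window = filt.window
        lam = cube.wavelengths
        sel = (lam >= window.lambda_min) & (lam <= window.lambda_max)
        if lam[sel].size < 2 or lam[0] > window.lambda_min or lam[-1] < window.lambda_max:
            raise ValueError("cube wavelength grid does not cover the filter window")
        lam_w = lam[sel]
        curve_t = realized_curve(filt, grid=lam_w).transmission
        inten = cube.data[:, :, sel]
    else:
        lam = cube.wavelengths
        lo, hi = filt.wavelengths[0], filt.wavelengths[-1]
        sel = (lam >= lo) & (lam <= hi)
        if lam[sel].size < 2 or lam[0] > lo or lam[-1] < hi:
            raise ValueError("cube wavelength grid does not cover the curve support")
        lam_w = lam[sel]
        curve_t = filt(lam_w)
        inten = cube.data[:, :, sel]
    qe = camera.qe_at(lam_w)
    electrons = camera.exposure * camera.pixel_area * np.trapezoid(
        inten * (curve_t * qe)[None, None, :], lam_w, axis=2)
    return camera.gain * electrons + camera.dark_offset


def acquire_frame(
    cube: SpectralCube,
    filt: FilterSetting | TransmissionCurve,
    camera: CameraModel,
    seed: int | np.random.Generator | None = None,
    add_noise: bool = True,
    quantize: bool = True,
) -> IntensityImage:
    """Simulate one camera frame of the scene through a filter.

    The realized DN image is drawn from a normal distribution around the
    expected signal with the photon-transfer variance, then clipped to
    the ADC range and quantized (round half to even).  Reproducible for
    a fixed seed.  ``add_noise=False``/``quantize=False`` yield the
    noise-free analog expectation used by the oracle-equivalence tests.
    """
    mu = expected_signal(cube, filt, camera)
    data = mu
    if add_noise:
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        data = rng.normal(mu, np.sqrt(noise_variance(mu, camera)))
    clipped = 0
    if quantize:
        raw = data
        data = np.clip(np.rint(raw), 0, camera.full_scale)
        clipped = int(np.sum((raw < 0) | (raw > camera.full_scale)))
        if clipped:
            log.debug("%d pixels clipped to the ADC range", clipped)
    meta = {"clipped_pixels": clipped, "noise": bool(add_noise),
            "quantized": bool(quantize)}
    if isinstance(filt, FilterSetting):
        meta["filter"] = filt.to_dict()
    return IntensityImage(data, exposure=camera.exposure, meta=meta)


def acquire_three(
    cube: SpectralCube,
    settings: dict[str, FilterSetting],
    camera: CameraModel,
    seed: int | np.random.Generator | None = None,
    add_noise: bool = True,
    quantize: bool = True,
) -> dict[str, IntensityImage]:
    """Acquire the sine, cosine and total frames of one hyperspectral cube.

    A single generator is threaded through the three frames so the
    triple is reproducible from one seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return {
        kind: acquire_frame(cube, settings[kind], camera, seed=rng,
                            add_noise=add_noise, quantize=quantize)
        for kind in ("sine", "cosine", "total")
    }


def phasor_spread(phasor: PhasorImage) -> float:
    """Sum of the standard deviations of G and S over valid pixels.

    The scalar cluster-spread statistic used to quantify phasor
    uncertainty as a function of light intensity.
    """
    return phasor.spread()


def predicted_phasor_spread(
    mu_total: float,
    fraction_sine: float,
    fraction_cosine: float,
    camera: CameraModel,
) -> float:
    """First-order propagation of the photon-transfer noise into (G, S).

    For a uniform-signal image with total-frame mean ``mu_total`` DN and
    sine/cosine frame fractions f, independent frame noise gives

        Var(G) = 4 [sigma_c^2 + f_c^2 sigma_t^2] / mu_t^2

    (S analogous); the predicted spread is SD(G) + SD(S).  This is the
    analytic curve that the Monte-Carlo spread is validated against.
    """
    if mu_total <= 0:
        raise ValueError("mu_total must be positive")
    var_t = noise_variance(mu_total, camera)
    out = 0.0
    for f in (fraction_cosine, fraction_sine):
        var_f = noise_variance(f * mu_total, camera)
        out += np.sqrt(4.0 * (var_f + f * f * var_t) / mu_total**2)
    return float(out)
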