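"""Self-contained simulation studies: analytic identities, spectral
resolution, noise limits, mixture recovery, and the water-uptake
time-series benchmark.

Each study builds its own synthetic inputs, runs the full
calibrate -> acquire -> phasor pipeline, and returns plain numbers, so
the same entry points back both the test suite and reproducibility
scripts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import analysis, camera, optics, phasor, synth

__all__ = [
    "flat_transmission_values",
    "monochromatic_modulus",
    "ResolutionResult",
    "resolution_sweep",
    "spread_vs_flux",
    "cluster_loss_flux",
    "mixture_recovery",
    "water_uptake_benchmark",
]


def flat_transmission_values(step: float = 1.0) -> np.ndarray:
    """Transmission at zero retardance across the 900-1600 nm range."""
    lam = np.arange(optics.DETECTION_RANGE[0],
                    optics.DETECTION_RANGE[1] + 0.5 * step, step)
    return np.asarray(optics.transmission(0.0, lam))


def monochromatic_modulus(
    line_nm: float = 1073.0,
    window: optics.SpectralWindow | None = None,
) -> float:
    """Phasor modulus of an on-grid delta line through exact filters.

    The three filtered integrals of a delta spectrum reduce to the
    filter transmissions at the line, so (G, S) = (cos x0, sin x0) and
    the modulus is 1 for any line position inside the window.
    """
    window = window or optics.SpectralWindow(900.0, 1200.0)
    lam = window.grid()
    inten = np.zeros_like(lam)
    idx = int(np.argmin(np.abs(lam - line_nm)))
    inten[idx] = 1.0
    spec = synth.Spectrum(lam, inten)
    curves = tuple(
        optics.ideal_filter_curve(window, kind, grid=lam)
        for kind in ("sine", "cosine", "total")
    )
    point = phasor.phasor_through_filters(spec, curves)
    return point.modulus


@dataclass(frozen=True)
class ResolutionResult:
    separations: np.ndarray
    centroid_distance: np.ndarray
    within_cluster_sd: np.ndarray
    separable: np.ndarray

    @property
    def smallest_separable(self) -> float:
        """Smallest separation (nm) below which no smaller one fails."""
        ok = self.separable
        order = np.argsort(self.separations)
        smallest = np.inf
        for i in order[::-1]:  # largest to smallest, stop at first failure
            if not ok[i]:
                break
            smallest = float(self.separations[i])
        return smallest


def _pixels_of_species(
    spectrum: synth.Spectrum,
    settings: dict,
    cam: camera.CameraModel,
    n_pixels: int,
    rng: np.random.Generator,
) -> phasor.PhasorImage:
    """Acquire a uniform n-pixel field of one spectrum with noise."""
    cube = synth.SpectralCube(
        np.broadcast_to(spectrum.intensity, (1, n_pixels, spectrum.wavelengths.size)).copy(),
        spectrum.wavelengths,
    )
    frames = camera.acquire_three(cube, settings, cam, seed=rng)
    signs = (settings["sine"].sign, settings["cosine"].sign)
    return phasor.phasor_from_frames(
        frames["sine"], frames["cosine"], frames["total"], signs=signs)


def resolution_sweep(
    separations=(10.0, 8.0, 6.0, 5.0, 4.0, 3.0),
    center: float = 1100.0,
    window_width: float = 240.0,
    fwhm: float = 30.0,
    flux: float = 1e11,
    n_pixels: int = 100,
    seed: int = 0,
    retarder: optics.RetarderModel | None = None,
) -> ResolutionResult:
    """Peak-separation sweep of two emission bands after spectral zoom-in.

    Two Gaussian emission spectra of equal width are placed
    symmetrically around ``center`` at each separation, imaged through
    retardance-calibrated sine/cosine/total filters over a window of
    ``window_width`` nm with the photon-transfer noise model, and their
    phasor clusters compared.  A separation counts as separable when the
    cluster-centroid distance exceeds twice the mean within-cluster
    standard deviation (SD taken as the per-cluster spread statistic).
    """
    window = optics.SpectralWindow(center - window_width / 2.0,
                                   center + window_width / 2.0)
    settings = optics.calibrate_filter_bank(window, retarder)
    cam = camera.CameraModel()
    grid = window.grid()
    rng = np.random.default_rng(seed)
    dist, sds, sep_ok = [], [], []
    for sep in separations:
        points = []
        spreads = []
        for offset in (-sep / 2.0, +sep / 2.0):
            spec = synth.gaussian_line(center + offset, fwhm, total_flux=flux,
                                       grid=grid)
            ph = _pixels_of_species(spec, settings, cam, n_pixels, rng)
            points.append(ph.mean_point())
            spreads.append(0.5 * ph.spread())  # mean of SD(G), SD(S)
        d = points[0].distance(points[1])
        sd = float(np.mean(spreads))
        dist.append(d)
        sds.append(sd)
        sep_ok.append(d > 2.0 * sd)
    return ResolutionResult(np.asarray(separations, float), np.asarray(dist),
                            np.asarray(sds), np.asarray(sep_ok))


def _gaussian_profile_scene(
    spectrum: synth.Spectrum, shape: tuple[int, int], mean_flux: float
) -> synth.SpectralCube:
    """Scene with a circular Gaussian intensity profile whose image-mean
    integrated flux equals ``mean_flux``."""
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    sigma = min(ny, nx) / 6.0
    prof = np.exp(-(((yy - ny / 2.0) ** 2 + (xx - nx / 2.0) ** 2)
                    / (2.0 * sigma**2)))
    prof *= mean_flux / (prof.mean() * spectrum.total_flux)
    return synth.SpectralCube(prof[:, :, None] * spectrum.intensity,
                              spectrum.wavelengths)


def spread_vs_flux(
    flux_levels,
    seed: int = 0,
    repeats: int = 3,
    shape: tuple[int, int] = (48, 48),
    window: optics.SpectralWindow | None = None,
) -> np.ndarray:
    """Mean phasor spread at each average photon flux (Gaussian-profile
    scene of a single emission band, ideal filters, full noise model)."""
    window = window or optics.SpectralWindow(900.0, 1600.0)
    grid = window.grid(2.0)
    spec = synth.fluorophore_spectrum(**synth.DEFECT_PAIR["pristine"],
                                      total_flux=1.0, grid=grid)
    curves = {k: optics.ideal_filter_curve(window, k, grid=grid)
              for k in ("sine", "cosine", "total")}
    cam = camera.CameraModel()
    rng = np.random.default_rng(seed)
    out = np.empty(len(flux_levels))
    for i, flux in enumerate(flux_levels):
        cube = _gaussian_profile_scene(spec, shape, flux)
        spreads = []
        for _ in range(repeats):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # all-invalid frames expected
                frames = {k: camera.acquire_frame(cube, curves[k], cam,
                                                  seed=rng)
                          for k in ("sine", "cosine", "total")}
                ph = phasor.phasor_from_frames(frames["sine"],
                                               frames["cosine"],
                                               frames["total"], min_total=1.0)
            # a flux too low to leave any valid pixel has, a fortiori,
            # no identifiable cluster
            spreads.append(ph.spread() if ph.valid.any() else np.nan)
        out[i] = float(np.mean(spreads))
    return out


def cluster_loss_flux(
    threshold: float = 0.5,
    flux_grid=None,
    seed: int = 0,
    repeats: int = 3,
) -> dict:
    """Photon flux below which the phasor no longer forms a cluster.

    The cluster-loss criterion is operationalized as the phasor spread
    exceeding ``threshold``; the crossing flux is interpolated on a log
    axis.  The result carries the crossing for neighbouring thresholds
    as a sensitivity report, since any scalar criterion for "no cluster
    observable" is a choice.
    """
    if flux_grid is None:
        flux_grid = np.logspace(7.0, 11.0, 9)
    flux_grid = np.asarray(flux_grid, float)
    spreads = spread_vs_flux(flux_grid, seed=seed, repeats=repeats)

    def crossing(thr: float) -> float:
        above = (spreads > thr) | np.isnan(spreads)
        if not above.any():
            return float("nan")
        if above.all():
            return float(flux_grid[-1])
        idx = int(np.nonzero(above)[0][-1])  # last flux with spread > thr
        if idx + 1 >= len(flux_grid):
            return float(flux_grid[idx])
        # log-linear interpolation between the bracketing levels
        x0, x1 = np.log10(flux_grid[idx]), np.log10(flux_grid[idx + 1])
        y0, y1 = spreads[idx], spreads[idx + 1]
        frac = (y0 - thr) / (y0 - y1)
        return float(10 ** (x0 + frac * (x1 - x0)))

    return {
        "flux_levels": flux_grid,
        "spreads": spreads,
        "threshold": threshold,
        "crossing_flux": crossing(threshold),
        "sensitivity": {thr: crossing(thr) for thr in (0.3, 0.5, 0.7)},
    }


def mixture_recovery(
    ratios=((50, 50), (75, 25), (90, 10), (95, 5)),
    flux: float = 1e11,
    n_pixels: int = 100,
    seed: int = 0,
    noise: bool = True,
    window: optics.SpectralWindow | None = None,
) -> dict:
    """Two-endmember unmixing of pristine/defect emitter mixtures.

    Mixtures at the given pristine:defect intensity ratios are imaged
    through ideal filters; endmember phasors come from the pure spectra
    via the exact transform.  Returns truth and recovered intensity
    fractions of the defect component.
    """
    window = window or optics.SpectralWindow(900.0, 1200.0)
    grid = window.grid()
    pristine = synth.fluorophore_spectrum(**synth.DEFECT_PAIR["pristine"],
                                          total_flux=1.0, grid=grid)
    defect = synth.fluorophore_spectrum(**synth.DEFECT_PAIR["defect"],
                                        total_flux=1.0, grid=grid)
    pair = analysis.EndmemberPair(
        phasor.spectral_phasor(pristine, window),
        phasor.spectral_phasor(defect, window),
    )
    curves = {k: optics.ideal_filter_curve(window, k, grid=grid)
              for k in ("sine", "cosine", "total")}
    cam = camera.CameraModel()
    rng = np.random.default_rng(seed)
    truth, recovered = [], []
    for r_pristine, r_defect in ratios:
        f_defect = r_defect / (r_pristine + r_defect)
        mix = pristine.scaled((1.0 - f_defect) * flux) + defect.scaled(
            f_defect * flux)
        if noise:
            cube = synth.SpectralCube(
                np.broadcast_to(mix.intensity, (1, n_pixels, grid.size)).copy(),
                grid)
            frames = {k: camera.acquire_frame(cube, curves[k], cam, seed=rng)
                      for k in ("sine", "cosine", "total")}
            ph = phasor.phasor_from_frames(frames["sine"], frames["cosine"],
                                           frames["total"])
            point = ph.mean_point()
        else:
            point = phasor.phasor_through_filters(mix, tuple(
                curves[k] for k in ("sine", "cosine", "total")))
        res = analysis.unmix_two(point, pair)
        truth.append(f_defect)
        recovered.append(res.intensity_fraction)
    return {"truth": np.asarray(truth), "recovered": np.asarray(recovered),
            "max_error": float(np.max(np.abs(np.asarray(truth)
                                             - np.asarray(recovered))))}


def water_uptake_benchmark(
    shape: tuple[int, int] = (24, 24),
    vein_onset: float = 60.0,
    lamina_onset: float = 180.0,
    rate: float = 1.0 / 120.0,
    frame_period: float = 5.0,
    duration: float = 420.0,
    regression_window: float = 60.0,
    reference_period: float = 30.0,
    seed: int = 0,
) -> dict:
    """End-to-end water-uptake pipeline on a vein/lamina toy leaf.

    A central vein (3-pixel column band) starts taking up water before
    the surrounding lamina; frames are acquired through ideal filters
    over the 900-1600 nm window with camera noise, and the full
    reference -> displacement -> trailing-OLS -> percentile-normalization
    pipeline runs downstream.  Returns the per-region argmax times of
    the mean normalized rate.
    """
    ny, nx = shape
    vein = np.zeros(shape, dtype=bool)
    vein[:, nx // 2 - 1: nx // 2 + 2] = True
    onset = np.where(vein, vein_onset, lamina_onset)
    window = optics.SpectralWindow(900.0, 1600.0)
    grid = window.grid(4.0)
    curves = {k: optics.ideal_filter_curve(window, k, grid=grid)
              for k in ("sine", "cosine", "total")}
    cam = camera.CameraModel(exposure=0.007)  # short reflectance exposure
    rng = np.random.default_rng(seed)
    series = []
    for t, cube in synth.water_uptake_series(
            shape, onset, np.full(shape, rate), frame_period=frame_period,
            duration=duration, illumination=1e11, grid=grid):
        frames = {k: camera.acquire_frame(cube, curves[k], cam, seed=rng)
                  for k in ("sine", "cosine", "total")}
        series.append((t, phasor.phasor_from_frames(
            frames["sine"], frames["cosine"], frames["total"])))
    reference = analysis.reference_phasor(series, t_ref=reference_period)
    times, disp, valid = analysis.phasor_displacement(series, reference)
    rates = analysis.rate_of_change(times, disp, valid,
                                    window=regression_window)
    rates = analysis.normalize_rates(rates)
    norm = rates.normalized
    vein_curve = np.array([frame[vein].mean() for frame in norm])
    lamina_curve = np.array([frame[~vein].mean() for frame in norm])
    return {
        "times": rates.times,
        "vein_rate": vein_curve,
        "lamina_rate": lamina_curve,
        "vein_peak_time": float(rates.times[int(np.argmax(vein_curve))]),
        "lamina_peak_time": float(rates.times[int(np.argmax(lamina_curve))]),
        "normalization": rates.normalization,
    }
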