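"""Phasor transform, distortion correction, spatial correction, gating."""

import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nirphasor import camera, optics, phasor, synth
from nirphasor.phasor import (CorrectionField, PhasorImage, PhasorPoint,
                              angular_color, apply_correction, distortion_map,
                              estimate_correction_field, phasor_from_frames,
                              phasor_histogram, phasor_through_filters,
                              polygon_gate, spectral_phasor)


def delta_spectrum(grid, line):
    inten = np.zeros_like(grid)
    inten[np.argmin(np.abs(grid - line))] = 1.0
    return synth.Spectrum(grid, inten)


class TestPhasorFromFrames:
    def test_spectrally_flat_signal_maps_to_origin(self):
        total = np.full((4, 4), 200.0)
        ph = phasor_from_frames(total / 2, total / 2, total)
        assert np.allclose(ph.g, 0.0) and np.allclose(ph.s, 0.0)
        assert ph.valid.all()

    def test_monochromatic_pixel_lands_on_unit_circle(self, window, grid):
        """A narrow line at phase x0 through exact filters gives
        (G, S) = (cos x0, sin x0) with modulus 1."""
        line = 1073.0
        x0 = window.phase(line)
        t_sin = optics.ideal_filter_curve(window, "sine", grid=grid)
        t_cos = optics.ideal_filter_curve(window, "cosine", grid=grid)
        i_tot = np.full((2, 2), 1000.0)
        ph = phasor_from_frames(i_tot * t_sin([line])[0],
                                i_tot * t_cos([line])[0], i_tot)
        assert ph.g[0, 0] == pytest.approx(np.cos(x0), abs=1e-12)
        assert ph.s[0, 0] == pytest.approx(np.sin(x0), abs=1e-12)
        assert ph.modulus[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_zero_total_pixel_is_invalid_not_nan(self):
        total = np.full((3, 3), 100.0)
        total[1, 1] = 0.0
        ph = phasor_from_frames(total / 2, total / 2, total, min_total=10.0)
        assert not ph.valid[1, 1]
        assert np.isfinite(ph.g).all()

    def test_outside_unit_circle_pixels_are_discarded(self):
        total = np.full((2, 2), 100.0)
        sine = np.full((2, 2), 60.0)
        cosine = np.full((2, 2), 60.0)
        cosine[0, 0] = 110.0  # G > 1.05: impossible spectrum, noise artifact
        ph = phasor_from_frames(sine, cosine, total, min_total=1.0)
        assert not ph.valid[0, 0]
        assert ph.valid[1, 1]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="share a shape"):
            phasor_from_frames(np.ones((2, 2)), np.ones((2, 2)),
                               np.ones((3, 3)))

    def test_all_invalid_warns(self):
        with pytest.warns(UserWarning, match="invalid"):
            phasor_from_frames(np.zeros((2, 2)), np.zeros((2, 2)),
                               np.zeros((2, 2)), min_total=10.0)

    def test_sine_sign_flip_negates_s_exactly(self):
        rng = np.random.default_rng(0)
        total = rng.uniform(100.0, 200.0, (5, 5))
        sine = rng.uniform(0.0, 1.0, (5, 5)) * total
        cosine = rng.uniform(0.0, 1.0, (5, 5)) * total
        plus = phasor_from_frames(sine, cosine, total, signs=(1, 1))
        minus = phasor_from_frames(sine, cosine, total, signs=(-1, 1))
        twice = phasor_from_frames(sine, cosine, total, signs=(1, 1))
        assert np.array_equal(minus.s, -plus.s)
        assert np.array_equal(minus.g, plus.g)
        assert np.array_equal(twice.s, plus.s)  # double negation is identity


class TestSpectralPhasor:
    def test_delta_at_window_center(self, window, grid):
        point = spectral_phasor(delta_spectrum(grid, 1050.0), window)
        assert point.g == pytest.approx(-1.0, abs=1e-12)
        assert point.s == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_matches_characteristic_function(self, window):
        """A Gaussian at the window center has S = 0 and
        G = -exp(-(2 pi sigma / width)^2 / 2)."""
        sigma = 12.0
        fine = np.arange(900.0, 1200.5, 0.5)
        spec = synth.gaussian_line(1050.0, sigma / synth._FWHM_TO_SIGMA,
                                   total_flux=1.0, grid=fine)
        point = spectral_phasor(spec, window)
        assert point.s == pytest.approx(0.0, abs=1e-9)
        assert point.g == pytest.approx(
            -np.exp(-(2 * np.pi * sigma / 300.0) ** 2 / 2.0), abs=1e-6)

    def test_zero_intensity_rejected(self, window, grid):
        with pytest.raises(ValueError, match="zero total intensity"):
            spectral_phasor(synth.Spectrum(grid, np.zeros_like(grid)), window)

    @given(a=st.floats(0.1, 10.0), b=st.floats(0.1, 10.0))
    def test_mixture_linearity(self, a, b):
        """The phasor of a non-negative mixture is the intensity-weighted
        combination of the component phasors (convexity)."""
        window = optics.SpectralWindow(900.0, 1200.0)
        grid = window.grid()
        s1 = synth.fluorophore_spectrum(985.0, 30.0, total_flux=1.0, grid=grid)
        s2 = synth.fluorophore_spectrum(1080.0, 45.0, total_flux=1.0, grid=grid)
        p1 = spectral_phasor(s1, window)
        p2 = spectral_phasor(s2, window)
        w1, w2 = a * s1.total_flux, b * s2.total_flux
        mix = spectral_phasor(s1.scaled(a) + s2.scaled(b), window)
        assert mix.g == pytest.approx((w1 * p1.g + w2 * p2.g) / (w1 + w2),
                                      abs=1e-9)
        assert mix.s == pytest.approx((w1 * p1.s + w2 * p2.s) / (w1 + w2),
                                      abs=1e-9)

    def test_modulus_bounded_by_one_for_nonnegative_spectra(self, window):
        rng = np.random.default_rng(11)
        grid = window.grid()
        for _ in range(20):
            spec = synth.Spectrum(grid, rng.uniform(0.0, 1.0, grid.size))
            assert spectral_phasor(spec, window).modulus <= 1.0 + 1e-12

    def test_modulus_one_only_for_monochromatic(self, window, grid):
        delta = spectral_phasor(delta_spectrum(grid, 1000.0), window)
        assert delta.modulus == pytest.approx(1.0, abs=1e-12)
        broad = spectral_phasor(
            synth.gaussian_line(1000.0, 30.0, grid=grid), window)
        assert broad.modulus < 1.0 - 1e-6


class TestPhasorThroughFilters:
    def test_ideal_curves_reproduce_exact_phasor(self, window, grid,
                                                 ideal_curves):
        spec = synth.fluorophore_spectrum(1010.0, 35.0, total_flux=1e10,
                                          grid=grid)
        via_filters = phasor_through_filters(
            spec, (ideal_curves["sine"], ideal_curves["cosine"],
                   ideal_curves["total"]))
        exact = spectral_phasor(spec, window)
        assert via_filters.g == pytest.approx(exact.g, abs=1e-12)
        assert via_filters.s == pytest.approx(exact.s, abs=1e-12)

    def test_calibrated_curves_displace_narrow_lines(self, window):
        """The realized cos(1/lambda) transmission shifts phasor points
        away from their ideal positions."""
        bank = optics.calibrate_filter_bank(window,
                                            optics.RetarderModel(None))
        curves = tuple(
            optics.realized_curve(bank[k], grid=window.grid())
            if k != "total" else optics.ideal_filter_curve(window, "total")
            for k in ("sine", "cosine", "total"))
        signs = (bank["sine"].sign, bank["cosine"].sign)
        fine = np.arange(900.0, 1200.25, 0.25)
        spec = synth.gaussian_line(1000.0, 2.0, grid=fine)
        realized = phasor_through_filters(spec, curves, signs=signs)
        ideal = spectral_phasor(spec, window)
        assert realized.distance(ideal) > 1e-3

    def test_displacement_shrinks_at_fixed_width_as_center_grows(self):
        """With a 100 nm window the phasor error of the realized filters
        falls as the center wavelength rises from 950 to 1450 nm."""
        displacements = []
        for center in (950.0, 1150.0, 1450.0):
            window = optics.SpectralWindow(center - 50.0, center + 50.0)
            bank = optics.calibrate_filter_bank(window,
                                                optics.RetarderModel(None))
            grid = window.grid()
            curves = tuple(
                optics.realized_curve(bank[k], grid=grid)
                if k != "total" else optics.ideal_filter_curve(window, "total")
                for k in ("sine", "cosine", "total"))
            signs = (bank["sine"].sign, bank["cosine"].sign)
            fine = np.arange(window.lambda_min, window.lambda_max + 0.125, 0.25)
            spec = synth.gaussian_line(center - 20.0, 2.0, grid=fine)
            realized = phasor_through_filters(spec, curves, signs=signs)
            displacements.append(realized.distance(
                spectral_phasor(spec, window)))
        assert displacements[0] > displacements[1] > displacements[2]


class TestDistortionMap:
    @pytest.fixture
    def calibrated(self, window):
        return optics.calibrate_filter_bank(window, optics.RetarderModel(None))

    def test_ideal_settings_have_zero_displacement(self, window):
        # emulate perfect filters by probing the correction built from a
        # bank whose realized curves ARE the ideal ones: displacement at
        # the knots of an identity table is zero by construction
        probes = np.arange(920.0, 1181.0, 20.0)
        x0 = window.phase(probes)
        ideal = np.column_stack([np.cos(x0), np.sin(x0)])
        corr = phasor.PhasorCorrection(probes, ideal, ideal.copy())
        assert np.all(corr.displacement == 0.0)

    def test_correction_exact_at_knots(self, window, calibrated):
        corr = distortion_map(window, calibrated, np.arange(920.0, 1181.0, 5.0))
        for lam, ideal, realized, _ in corr.table()[::10]:
            fixed = corr.apply(realized)
            assert fixed.distance(ideal) < 1e-3

    def test_off_knot_correction_reduces_displacement(self, window, calibrated):
        corr = distortion_map(window, calibrated, np.arange(920.0, 1181.0, 5.0))
        lam0 = 1042.5  # halfway between knots
        x0 = window.phase(lam0)
        ideal = PhasorPoint(np.cos(x0), np.sin(x0))
        fine = np.arange(900.0, 1200.25, 0.25)
        curves = tuple(
            optics.realized_curve(calibrated[k], grid=window.grid())
            if k != "total" else optics.ideal_filter_curve(window, "total")
            for k in ("sine", "cosine", "total"))
        signs = (calibrated["sine"].sign, calibrated["cosine"].sign)
        realized = phasor_through_filters(
            synth.gaussian_line(lam0, 1.0, grid=fine), curves, signs=signs)
        before = realized.distance(ideal)
        after = corr.apply(realized).distance(ideal)
        assert after < 0.1 * before


class TestCorrectionField:
    def test_uniform_noiseless_reference_yields_zero_field(self):
        ph = PhasorImage(np.full((6, 6), 0.4), np.full((6, 6), -0.1),
                         np.ones((6, 6), bool))
        field = estimate_correction_field([ph, ph])
        assert np.allclose(field.dg, 0.0) and np.allclose(field.ds, 0.0)

    def test_planar_tilt_recovered_exactly(self):
        yy, xx = np.mgrid[0:8, 0:8]
        tilt = 0.01 * (xx - xx.mean())
        ph = PhasorImage(0.4 + tilt, np.full((8, 8), -0.1),
                         np.ones((8, 8), bool))
        field = estimate_correction_field([ph])
        assert np.allclose(field.dg, tilt, atol=1e-9)
        corrected = apply_correction(ph, field)
        assert corrected.spread() < ph.spread()

    def test_mostly_invalid_reference_rejected(self):
        valid = np.zeros((4, 4), bool)
        valid[0, 0] = True
        ph = PhasorImage(np.zeros((4, 4)), np.zeros((4, 4)), valid)
        with pytest.raises(ValueError, match="50%"):
            estimate_correction_field([ph])


class TestAngularColorAndGates:
    def test_constant_phase_image_gets_one_index(self):
        ph = PhasorImage(np.full((3, 3), 0.5), np.full((3, 3), 0.5),
                         np.ones((3, 3), bool))
        idx = angular_color(ph)
        assert len(np.unique(idx)) == 1

    def test_wraparound_at_pi(self):
        ph = PhasorImage(np.array([[-1.0, -1.0]]),
                         np.array([[0.0, -0.0]]),  # theta = +pi vs -pi
                         np.ones((1, 2), bool))
        idx = angular_color(ph, n_colors=16)
        assert idx[0, 0] == idx[0, 1]

    def test_invalid_pixels_get_sentinel(self):
        valid = np.array([[True, False]])
        ph = PhasorImage(np.array([[0.5, 0.5]]), np.array([[0.0, 0.0]]), valid)
        idx = angular_color(ph)
        assert idx[0, 1] == -1

    def test_polygon_covering_disk_labels_all_valid(self):
        rng = np.random.default_rng(2)
        g = rng.uniform(-0.5, 0.5, (8, 8))
        s = rng.uniform(-0.5, 0.5, (8, 8))
        ph = PhasorImage(g, s, np.ones((8, 8), bool))
        square = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], float)
        labels = polygon_gate(ph, [(1, square)])
        assert np.all(labels == 1)

    def test_disjoint_polygons_give_disjoint_labels(self):
        ph = PhasorImage(np.array([[-0.5, 0.5]]), np.array([[0.0, 0.0]]),
                         np.ones((1, 2), bool))
        left = np.array([[-0.9, -0.2], [-0.1, -0.2], [-0.1, 0.2], [-0.9, 0.2]])
        right = left + [1.0, 0.0]
        labels = polygon_gate(ph, [(1, left), (2, right)])
        assert labels[0, 0] == 1 and labels[0, 1] == 2

    def test_two_polymer_scene_classified_by_gates(self, cam):
        """End-to-end: render the two-polymer scene, acquire with noise
        at high SNR, gate the phasor clusters, and recover >= 99% of the
        ground-truth labels."""
        window = optics.SpectralWindow(900.0, 1600.0)
        grid = window.grid(2.0)
        flux = 1e11
        specs = {
            1: synth.reflectance_spectrum("polymerA", grid=grid, scale=flux),
            2: synth.reflectance_spectrum("polymerB", grid=grid, scale=flux),
        }
        scene = synth.SceneSpec(
            (32, 32), [synth.Region(("disk", (16, 8), 6), specs[1], 1),
                       synth.Region(("disk", (16, 24), 6), specs[2], 2)])
        cube = synth.render_scene(scene)
        curves = {k: optics.ideal_filter_curve(window, k, grid=grid)
                  for k in ("sine", "cosine", "total")}
        cam_fast = camera.CameraModel(exposure=0.007)
        rng = np.random.default_rng(4)
        frames = {k: camera.acquire_frame(cube, curves[k], cam_fast, seed=rng)
                  for k in curves}
        ph = phasor_from_frames(frames["sine"], frames["cosine"],
                                frames["total"])
        truth = synth.label_image(scene)
        gates = []
        for label, spec in specs.items():
            p = spectral_phasor(spec, window)
            h = 0.006  # ~8x the within-cluster SD, below half the separation
            gates.append((label, np.array(
                [[p.g - h, p.s - h], [p.g + h, p.s - h],
                 [p.g + h, p.s + h], [p.g - h, p.s + h]])))
        labels = polygon_gate(ph, gates)
        in_regions = truth > 0
        agreement = np.mean(labels[in_regions] == truth[in_regions])
        assert agreement >= 0.99


class TestHistogram:
    def test_single_point_image_fills_one_bin(self):
        ph = PhasorImage(np.full((4, 4), 0.25), np.full((4, 4), -0.25),
                         np.ones((4, 4), bool))
        counts, _, _ = phasor_histogram(ph, bins=32)
        assert (counts > 0).sum() == 1
        assert counts.sum() == 16

    def test_counts_conserve_valid_pixels(self):
        rng = np.random.default_rng(3)
        valid = rng.uniform(size=(10, 10)) > 0.3
        ph = PhasorImage(rng.uniform(-0.9, 0.9, (10, 10)),
                         rng.uniform(-0.9, 0.9, (10, 10)), valid)
        counts, _, _ = phasor_histogram(ph, bins=16)
        assert counts.sum() == valid.sum()

    def test_mirrored_data_mirror_the_histogram(self):
        g = np.array([[0.375, -0.375]])  # mirror-symmetric bin centers
        s = np.array([[0.25, 0.25]])
        ph = PhasorImage(g, s, np.ones((1, 2), bool))
        counts, _, _ = phasor_histogram(ph, bins=8)
        assert np.array_equal(counts, counts[::-1, :])
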