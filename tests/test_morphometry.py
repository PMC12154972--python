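import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from dermometry.images import CalibratedImage, Polyline
from dermometry.morphometry import (
    bundle_thickness,
    d_band_period,
    linearity_index,
    measure_fibrils,
    perpendicular_transect,
    sample_profile,
    trace_centerline,
)
from dermometry.synthetic import SynthTemParams, generate_tem_bundle

from conftest import straight_ribbon


class TestLinearityIndex:
    def test_collinear_points_give_one(self):
        assert linearity_index(Polyline([[0, 0], [0, 5], [0, 9]])) == 1.0

    def test_semicircle_gives_pi_over_two(self):
        theta = np.linspace(0, np.pi, 1000)
        pts = np.column_stack((10 * np.sin(theta), 10 * np.cos(theta)))
        assert linearity_index(Polyline(pts)) == pytest.approx(np.pi / 2, rel=1e-3)

    def test_sinusoid_matches_quadrature(self):
        A, lam = 100.0, 1000.0
        x = np.linspace(0, lam, 2000)
        pts = np.column_stack((A * np.sin(2 * np.pi * x / lam), x))
        k = 2 * np.pi / lam
        arc, _ = quad(lambda t: math.sqrt(1 + (A * k * math.cos(k * t)) ** 2), 0, lam)
        assert linearity_index(Polyline(pts)) == pytest.approx(arc / lam, rel=1e-3)

    def test_closed_path_fails(self):
        pts = [[0, 0], [0, 5], [5, 5], [0, 0]]
        with pytest.raises(ValueError, match="coincide"):
            linearity_index(Polyline(pts))

    @given(
        angle=st.floats(0, 2 * math.pi),
        scale=st.floats(0.1, 50),
        dr=st.floats(-100, 100),
        dc=st.floats(-100, 100),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_similarity_invariance(self, angle, scale, dr, dc):
        """Rotation, translation and uniform scaling leave the index fixed."""
        rng = np.random.default_rng(5)
        pts = np.cumsum(rng.normal(0, 1, (12, 2)), axis=0)
        base = linearity_index(Polyline(pts))
        rot = np.array(
            [[math.cos(angle), -math.sin(angle)], [math.sin(angle), math.cos(angle)]]
        )
        moved = scale * pts @ rot.T + [dr, dc]
        assert linearity_index(Polyline(moved)) == pytest.approx(base, rel=1e-9)


class TestBundleThickness:
    def test_straight_ribbon_width_recovered(self):
        img = straight_ribbon(width_px=20, pixel_size_nm=10.0)
        axis = Polyline([[31.5, 10.0], [31.5, 117.0]])
        got = bundle_thickness(img, axis)
        assert got == pytest.approx(200.0, abs=10.0)  # within one pixel

    def test_calibration_linearity(self):
        """Halving the pixel size halves the physical width."""
        img5 = straight_ribbon(width_px=20, pixel_size_nm=5.0)
        axis = Polyline([[31.5, 10.0], [31.5, 117.0]])
        assert bundle_thickness(img5, axis) == pytest.approx(100.0, abs=5.0)

    def test_wavy_bundle_matches_ground_truth(self, tem_bundle):
        _, image, truth = tem_bundle
        got = bundle_thickness(image, truth.centerline)
        assert got == pytest.approx(truth.true_bundle_thickness_nm, rel=0.05)

    def test_blank_image_fails(self):
        img = CalibratedImage(np.full((64, 128), 0.85), 10.0, "TEM")
        axis = Polyline([[31.5, 10.0], [31.5, 117.0]])
        with pytest.raises(ValueError, match="probes|bundle"):
            bundle_thickness(img, axis)


def square_wave_profile(fibril_nm=50, gap_nm=10, n=4):
    """Noiseless alternating dark/bright transect at 1 nm per pixel,
    gaps at both ends."""
    gap = np.full(gap_nm, 0.85)
    fib = np.full(fibril_nm, 0.35)
    parts = [gap]
    for _ in range(n):
        parts += [fib, gap]
    return np.concatenate(parts)


class TestMeasureFibrils:
    def test_square_wave_widths_recovered(self, fibril_field):
        vals = square_wave_profile()
        # wrap as a TransectProfile via a synthetic 3-row image
        img = CalibratedImage(np.tile(vals, (3, 1)), pixel_size=1.0, modality="TEM")
        prof = sample_profile(img, (1.0, 0.0), (1.0, len(vals) - 1.0), step_px=0.5)
        seg = measure_fibrils(prof)
        assert len(seg.diameters_nm) == 4
        assert np.allclose(seg.diameters_nm, 50.0, atol=1.0)
        assert np.allclose(seg.gaps_nm, 10.0, atol=1.0)

    def test_constant_profile_fails(self):
        img = CalibratedImage(np.full((3, 100), 0.6), pixel_size=1.0, modality="TEM")
        prof = sample_profile(img, (1.0, 0.0), (1.0, 99.0))
        with pytest.raises(ValueError, match="no fibrils"):
            measure_fibrils(prof)

    def test_synthetic_transect_matches_truth(self, fibril_field):
        params, image, truth = fibril_field
        p0, p1 = perpendicular_transect(image, truth.centerline, 0.5)
        seg = measure_fibrils(sample_profile(image, p0, p1))
        assert np.mean(seg.diameters_nm) == pytest.approx(
            np.mean(truth.true_fibril_diameters_nm), rel=0.05
        )
        assert np.mean(seg.gaps_nm) == pytest.approx(
            np.mean(truth.true_gaps_nm), rel=0.15
        )

    def test_single_fibril_has_no_gaps(self, dband_fibril):
        _, image, truth = dband_fibril
        p0, p1 = perpendicular_transect(image, truth.centerline, 0.5)
        seg = measure_fibrils(sample_profile(image, p0, p1))
        assert len(seg.diameters_nm) == 1
        assert seg.gaps_nm == []


class TestDBandPeriod:
    def test_pure_sinusoid_period_recovered(self):
        # period 30 px at 2 nm/px -> 60 nm
        x = np.arange(512)
        row = 0.6 + 0.2 * np.cos(2 * np.pi * x / 30.0)
        img = CalibratedImage(np.tile(row, (9, 1)), pixel_size=2.0, modality="TEM")
        axis = Polyline([[4.0, 0.0], [4.0, 511.0]])
        est = d_band_period(img, axis)
        assert est.period_nm == pytest.approx(60.0, rel=0.02)
        assert not est.low_confidence

    def test_constant_profile_fails(self):
        img = CalibratedImage(np.full((9, 256), 0.6), pixel_size=2.0, modality="TEM")
        axis = Polyline([[4.0, 0.0], [4.0, 255.0]])
        with pytest.raises(ValueError):
            d_band_period(img, axis)

    def test_profile_shorter_than_five_periods_fails(self):
        x = np.arange(100)
        row = 0.6 + 0.2 * np.cos(2 * np.pi * x / 30.0)
        img = CalibratedImage(np.tile(row, (9, 1)), pixel_size=2.0, modality="TEM")
        axis = Polyline([[4.0, 0.0], [4.0, 99.0]])
        with pytest.raises(ValueError, match="periods"):
            d_band_period(img, axis)

    def test_synthetic_fibril_at_67nm(self):
        p = SynthTemParams(
            image_size=(64, 352),
            pixel_size_nm=2.0,
            fibril_diameter_nm=80.0,
            interfibrillar_gap_nm=20.0,
            n_fibrils=1,
            d_period_nm=67.0,
            d_band_contrast=0.4,
            centerline_amplitude_nm=10.0,
            centerline_wavelength_nm=1500.0,
            seed=8,
        )
        image, truth = generate_tem_bundle(p)
        est = d_band_period(image, truth.centerline)
        assert est.period_nm == pytest.approx(67.0, rel=0.02)

    def test_invariant_under_affine_intensity_rescaling(self, dband_fibril):
        _, image, truth = dband_fibril
        base = d_band_period(image, truth.centerline).period_nm
        rescaled = CalibratedImage(
            np.clip(0.2 + 0.6 * image.intensities, 0, 1), image.pixel_size, "TEM"
        )
        got = d_band_period(rescaled, truth.centerline).period_nm
        assert got == pytest.approx(base, rel=1e-6)


class TestTraceCenterline:
    def test_straight_ribbon_traces_straight(self):
        img = straight_ribbon(width_px=20, pixel_size_nm=10.0)
        traced = trace_centerline(img, (31, 64))
        assert linearity_index(traced) <= 1.02

    def test_wavy_bundle_linearity_within_5pct(self, tem_bundle):
        _, image, truth = tem_bundle
        mid = truth.centerline.points[len(truth.centerline) // 2]
        traced = trace_centerline(image, (int(mid[0]), int(mid[1])))
        assert linearity_index(traced) == pytest.approx(
            truth.true_linearity_index, rel=0.05
        )

    def test_seed_on_background_fails(self, tem_bundle):
        _, image, _ = tem_bundle
        with pytest.raises(ValueError, match="background"):
            trace_centerline(image, (2, 2))


class TestScaleEquivariance:
    def test_nm_outputs_scale_with_pixel_size(self, dband_fibril):
        """Same raster at doubled pixel size doubles every nm output."""
        _, image, truth = dband_fibril
        doubled = CalibratedImage(image.intensities, image.pixel_size * 2, "TEM")
        base = d_band_period(image, truth.centerline).period_nm
        assert d_band_period(doubled, truth.centerline).period_nm == pytest.approx(
            2 * base, rel=1e-9
        )
        p0, p1 = perpendicular_transect(image, truth.centerline, 0.5)
        d1 = np.mean(measure_fibrils(sample_profile(image, p0, p1)).diameters_nm)
        d2 = np.mean(measure_fibrils(sample_profile(doubled, p0, p1)).diameters_nm)
        assert d2 == pytest.approx(2 * d1, rel=1e-9)
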