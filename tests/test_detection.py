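"""Line detection: focus projection, profiles, detrending, centre picking,
spacings and the spectral period cross-check."""

import numpy as np
import pytest
from scipy import ndimage

from dentinchron.detect import (
    detect_line_centers,
    detrend,
    estimate_period_spectral,
    extract_profile,
    focus_project,
    measure_glg_thickness,
    spacings_from_centers,
)
from dentinchron.model import (
    DetectionParams,
    GrowthPath,
    ImageWithScale,
    LineCenters,
    Profile,
    ValidationError,
)
from dentinchron.simulate import render_profile


def renewal_centers(rng, n=200, mean=1.65, cv=0.1):
    sig2 = np.log1p(cv**2)
    sp = rng.lognormal(np.log(mean) - sig2 / 2, np.sqrt(sig2), n)
    return np.cumsum(sp) - sp / 2, sp


class TestFocusProject:
    def test_single_plane_identity(self, rng):
        img = rng.random((1, 40, 60))
        out = focus_project(ImageWithScale(img, 0.1))
        np.testing.assert_allclose(out.pixels, img[0])

    def test_constant_stack_stays_constant(self):
        img = np.full((5, 30, 30), 0.7)
        out = focus_project(ImageWithScale(img, 0.1))
        np.testing.assert_allclose(out.pixels, 0.7)

    def test_striped_sharpness_recovers_composite(self, rng):
        """Plane k sharp only in stripe k -> projection ~ all-sharp image."""
        base = rng.random((60, 90))
        stack = np.empty((3, 60, 90))
        for k in range(3):
            blurred = ndimage.gaussian_filter(base, 3.0)
            plane = blurred.copy()
            plane[:, k * 30 : (k + 1) * 30] = base[:, k * 30 : (k + 1) * 30]
            stack[k] = plane
        out = focus_project(ImageWithScale(stack, 0.1))

        def corr(a, b):
            return np.corrcoef(a.ravel(), b.ravel())[0, 1]

        assert corr(out.pixels, base) > max(corr(stack[k], base) for k in range(3))
        assert corr(out.pixels, base) > 0.95


class TestExtractProfile:
    def _band_image(self, period_px=10, w=400, h=60):
        x = np.arange(w)
        row = 0.5 + 0.4 * np.cos(2 * np.pi * x / period_px)
        return ImageWithScale(np.tile(row, (h, 1)), um_per_px=0.1)

    def test_vertical_bands_give_expected_period(self):
        img = self._band_image()
        path = GrowthPath([[0.0, 30.0], [399.0, 30.0]])
        prof = extract_profile(img, path, normal_window_px=3)
        period = estimate_period_spectral(detrend(prof, 10.0), (0.5, 2.0))
        assert period == pytest.approx(1.0, rel=0.01)

    def test_step_longer_than_path_yields_endpoints(self):
        img = self._band_image()
        prof = extract_profile(img, GrowthPath([[0.0, 10.0], [50.0, 10.0]]), step_um=99.0)
        assert prof.n == 2
        assert prof.s_um[0] == 0.0 and prof.s_um[-1] == pytest.approx(5.0)

    def test_reversed_path_reverses_profile(self):
        img = self._band_image()
        path = GrowthPath([[3.0, 20.0], [390.0, 20.0]])
        a = extract_profile(img, path)
        b = extract_profile(img, path.reversed())
        np.testing.assert_allclose(a.intensity, b.intensity[::-1], atol=1e-9)

    def test_path_outside_image_names_vertex(self):
        img = self._band_image()
        with pytest.raises(ValidationError, match="vertex 1"):
            extract_profile(img, GrowthPath([[0.0, 10.0], [1000.0, 10.0]]))


class TestDetrend:
    def test_sine_amplitude_preserved(self):
        s = np.arange(0, 100, 0.1)
        prof = Profile(s, np.sin(2 * np.pi * s / 1.65))
        flat = detrend(prof, 20.0)
        interior = flat.intensity[200:-200]
        # running-mean attenuation of a 1.65 μm sine over 20 μm is ~sinc(12.1) < 3%
        assert interior.max() == pytest.approx(1.0, rel=0.05)

    def test_linear_ramp_removed(self):
        s = np.arange(0, 50, 0.1)
        flat = detrend(Profile(s, 0.02 * s + 3.0), 10.0)
        assert np.abs(flat.intensity[100:-100]).max() < 1e-6

    def test_zero_mean_periodic_unchanged(self):
        s = np.arange(0, 100, 0.1)
        y = 0.3 * np.sin(2 * np.pi * s / 2.0)
        flat = detrend(Profile(s, y), 30.0)
        np.testing.assert_allclose(flat.intensity[300:-300], y[300:-300], atol=0.015)

    def test_window_shorter_than_three_samples_rejected(self):
        s = np.arange(0, 10, 0.5)
        with pytest.raises(ValidationError):
            detrend(Profile(s, np.ones_like(s)), 0.6)


class TestDetectCenters:
    def test_noiseless_centres_recovered_precisely(self):
        truth = 1.65 * np.arange(1, 101)
        prof = render_profile(truth, 1.65 * 101)
        centers = detect_line_centers(detrend(prof, 20.0), DetectionParams())
        assert centers.n == 100
        assert np.max(np.abs(centers.s_um - truth)) < 0.1

    def test_constant_profile_yields_nothing(self):
        s = np.arange(0, 50, 0.1)
        centers = detect_line_centers(Profile(s, np.ones_like(s)), DetectionParams())
        assert centers.n == 0

    def test_noisy_profile_high_recall_low_spurious(self, rng):
        truth, _ = renewal_centers(rng, n=200, cv=0.1)
        # noise sd = 0.2 x line amplitude
        prof = render_profile(truth, truth[-1] + 2, noise_sd=0.05, rng=rng)
        centers = detect_line_centers(detrend(prof, 20.0), DetectionParams())
        d = np.abs(centers.s_um[None, :] - truth[:, None])
        matched = (d.min(axis=1) < 0.4).mean()
        spurious = (d.min(axis=0) >= 0.4).mean()
        assert matched >= 0.95
        assert spurious <= 0.02

    def test_translation_and_intensity_scale_equivariance(self, rng):
        truth, _ = renewal_centers(rng, n=120)
        prof = render_profile(truth, truth[-1] + 2)
        flat = detrend(prof, 20.0)
        base = detect_line_centers(flat, DetectionParams())
        shifted = Profile(flat.s_um + 5.0, flat.intensity)
        c2 = detect_line_centers(shifted, DetectionParams())
        np.testing.assert_allclose(c2.s_um, base.s_um + 5.0, atol=1e-9)
        scaled = Profile(flat.s_um, flat.intensity * 3.7)
        c3 = detect_line_centers(scaled, DetectionParams())
        np.testing.assert_allclose(c3.s_um, base.s_um, atol=1e-9)


class TestSpacings:
    def test_midpoint_arithmetic(self):
        c = LineCenters(np.array([0.0, 1.5, 3.5]), np.ones(3))
        ms = spacings_from_centers(c, ("W", "a"))
        assert [m.spacing_um for m in ms] == [1.5, 2.0]
        assert [m.position_um for m in ms] == [0.75, 2.5]

    def test_cardinality_and_equal_spacing(self):
        c = LineCenters(1.65 * np.arange(365), np.ones(365))
        ms = spacings_from_centers(c, ("W", "a"))
        assert len(ms) == 364
        assert all(m.spacing_um == pytest.approx(1.65) for m in ms)

    def test_too_few_centres_rejected(self):
        with pytest.raises(ValidationError):
            spacings_from_centers(LineCenters(np.array([1.0]), np.ones(1)), ("W", "a"))


class TestThicknessAndPeriod:
    def test_thickness_is_arclength_difference(self):
        s = np.arange(0, 600, 0.1)
        prof = Profile(s, np.ones_like(s))
        assert measure_glg_thickness(prof, 10.0, 492.0) == pytest.approx(482.00)
        with pytest.raises(ValidationError):
            measure_glg_thickness(prof, 50.0, 50.0)
        with pytest.raises(ValidationError):
            measure_glg_thickness(prof, -1.0, 100.0)

    def test_curved_path_longer_than_chord(self):
        img = ImageWithScale(np.random.default_rng(0).random((200, 200)), 0.1)
        bent = GrowthPath([[10.0, 10.0], [100.0, 150.0], [190.0, 10.0]])
        prof = extract_profile(img, bent)
        chord_um = np.hypot(180.0, 0.0) * 0.1
        assert prof.length_um > chord_um

    def test_pure_sine_period(self):
        s = np.arange(0, 120, 0.1)
        prof = Profile(s, np.sin(2 * np.pi * s / 2.31))
        assert estimate_period_spectral(prof, (1.0, 3.0)) == pytest.approx(2.31, abs=0.01)

    def test_renewal_profile_period_near_truth(self, rng):
        truth, sp = renewal_centers(rng, n=300, cv=0.05)
        prof = render_profile(truth, truth[-1] + 2)
        per = estimate_period_spectral(detrend(prof, 20.0), (1.0, 3.0))
        assert per == pytest.approx(sp.mean(), rel=0.02)

    def test_white_noise_has_no_admissible_peak(self, rng):
        prof = Profile(np.arange(0, 120, 0.1), rng.normal(0, 1, 1200))
        with pytest.raises(ValidationError, match="no admissible"):
            estimate_period_spectral(prof, (1.0, 3.0))
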