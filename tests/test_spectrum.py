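"""Cross-peak synthesis, normalization, intensity matching and slices."""

import numpy as np
import pytest

import coilpeaks as cp
from coilpeaks.spectrum import SIGMA_PER_FWHM


def _moments_1d(x, w):
    w = np.clip(w, 0, None)
    mu = np.sum(x * w) / np.sum(w)
    var = np.sum((x - mu) ** 2 * w) / np.sum(w)
    return mu, np.sqrt(var)


@pytest.fixture()
def axes():
    return (
        cp.Axis.from_range("13C-CA", 45.0, 61.0, 0.1),
        cp.Axis.from_range("13C-CB", 10.0, 27.0, 0.1),
    )


class TestBuildCrosspeak:
    def test_single_pair_gives_gaussian_at_center(self, axes):
        a1, a2 = axes
        spec = cp.build_crosspeak(np.array([[53.0, 18.0]]), a1, a2,
                                  cp.BroadeningSpec((1.5, 1.5)))
        i, j = np.unravel_index(np.argmax(spec.intensity), spec.intensity.shape)
        assert a1.ppm()[j] == pytest.approx(53.0, abs=0.051)
        assert a2.ppm()[i] == pytest.approx(18.0, abs=0.051)
        # marginal widths match the broadening FWHM (within binning error)
        mu, sd = _moments_1d(a1.ppm(), spec.intensity.sum(axis=0))
        assert sd * 2.3548 == pytest.approx(1.5, abs=0.05)

    def test_two_resolved_pairs_equal_integrals(self, axes):
        # closed-form two-Gaussian oracle: equal weights, 6 ppm apart
        a1, a2 = axes
        spec = cp.build_crosspeak(
            np.array([[50.0, 18.0], [56.0, 18.0]]), a1, a2, cp.BroadeningSpec((1.5, 1.5))
        )
        left = spec.roi_integral(((45.0, 53.0), (10.0, 27.0)))
        right = spec.roi_integral(((53.0, 61.0), (10.0, 27.0)))
        assert left == pytest.approx(right, rel=1e-6)

    def test_integral_proportional_to_conformer_count(self, axes):
        a1, a2 = axes
        rng = np.random.default_rng(0)
        pts = rng.normal([53.0, 18.0], 0.5, size=(100, 2))
        s100 = cp.build_crosspeak(pts, a1, a2)
        s50 = cp.build_crosspeak(pts[:50], a1, a2)
        assert s100.integral() == pytest.approx(100 * s100.pixel_area, rel=1e-6)
        assert s50.integral() == pytest.approx(50 * s50.pixel_area, rel=1e-6)

    def test_axis_swap_transposes_grid(self, axes):
        a1, a2 = axes
        pts = np.array([[53.0, 18.0], [55.0, 20.0], [51.0, 16.0]])
        fwd = cp.build_crosspeak(pts, a1, a2, cp.BroadeningSpec((1.5, 2.0)))
        rev = cp.build_crosspeak(pts[:, ::-1], a2, a1, cp.BroadeningSpec((2.0, 1.5)))
        np.testing.assert_allclose(rev.intensity, fwd.intensity.T, rtol=1e-9)

    def test_out_of_grid_error_and_clip_modes(self, axes):
        a1, a2 = axes
        bad = np.array([[40.0, 18.0]])
        with pytest.raises(cp.ValidationError):
            cp.build_crosspeak(bad, a1, a2)
        with pytest.warns(UserWarning, match="clipping"):
            spec = cp.build_crosspeak(bad, a1, a2, on_out_of_grid="clip")
        assert spec.integral() > 0

    def test_broadening_monotonicity(self, axes):
        a1, a2 = axes
        pts = np.array([[53.0, 18.0]])
        maxima = []
        for fwhm in (1.0, 1.5, 2.5, 4.0):
            s = cp.normalize_integral(
                cp.build_crosspeak(pts, a1, a2, cp.BroadeningSpec((fwhm, fwhm)))
            )
            maxima.append(s.intensity.max())
        assert all(a >= b for a, b in zip(maxima, maxima[1:]))


class TestNormalizeIntegral:
    def test_definition_idempotence_scale_invariance(self, single_gauss_spectrum):
        s, _ = single_gauss_spectrum
        n1 = cp.normalize_integral(s)
        assert n1.integral() == pytest.approx(1.0, rel=1e-9)
        n2 = cp.normalize_integral(n1)
        np.testing.assert_allclose(n2.intensity, n1.intensity, rtol=1e-12)
        n3 = cp.normalize_integral(s.scaled(10.0))
        np.testing.assert_allclose(n3.intensity, n1.intensity, rtol=1e-12)

    def test_all_zero_rejected(self, axes):
        a1, a2 = axes
        zero = cp.Spectrum2D(a1, a2, np.zeros((a2.n_points, a1.n_points)))
        with pytest.raises(cp.DegenerateInputError):
            cp.normalize_integral(zero)


class TestMatchIntensity:
    def test_identity_and_linearity(self, single_gauss_spectrum):
        s, _ = single_gauss_spectrum
        roi = ((50.0, 56.0), (15.0, 22.0))
        factor, _ = cp.match_intensity(s, s, roi)
        assert factor == pytest.approx(1.0, rel=1e-12)
        factor2, scaled = cp.match_intensity(s, s.scaled(2.0), roi)
        assert factor2 == pytest.approx(0.5, rel=1e-12)
        assert scaled.roi_integral(roi) == pytest.approx(s.roi_integral(roi), rel=1e-9)

    def test_direct_quotient(self, single_gauss_spectrum):
        s, _ = single_gauss_spectrum
        roi = ((50.0, 56.0), (15.0, 22.0))
        ref = s.scaled(10.0 / s.roi_integral(roi))
        tgt = s.scaled(5.0 / s.roi_integral(roi))
        factor, _ = cp.match_intensity(ref, tgt, roi)
        assert factor == pytest.approx(2.0, rel=1e-9)

    def test_zero_target_roi_rejected(self, single_gauss_spectrum):
        s, _ = single_gauss_spectrum
        zero = s.scaled(0.0)
        with pytest.raises(cp.DegenerateInputError):
            cp.match_intensity(s, zero, ((50.0, 56.0), (15.0, 22.0)))


class TestExtractSlice:
    def test_slice_through_center_preserves_fwhm(self, single_gauss_spectrum):
        s, truth = single_gauss_spectrum
        ppm, prof = cp.extract_slice(s, "axis2", 18.5)
        mu, sd = _moments_1d(ppm, prof)
        assert mu == pytest.approx(53.0, abs=0.05)
        assert sd == pytest.approx(3.0 * SIGMA_PER_FWHM, abs=0.05)
        assert prof.max() == pytest.approx(1.0)

    def test_half_maximum_at_center_plus_half_fwhm(self, single_gauss_spectrum):
        # Gaussian closed form: intensity at center +/- FWHM/2 is half the peak
        s, _ = single_gauss_spectrum
        i0 = s.axis2.index_of(18.5)
        i_half = s.axis2.index_of(18.5 + 1.5)
        j0 = s.axis1.index_of(53.0)
        assert s.intensity[i_half, j0] == pytest.approx(0.5 * s.intensity[i0, j0], rel=1e-3)

    def test_out_of_range_names_bounds(self, single_gauss_spectrum):
        s, _ = single_gauss_spectrum
        with pytest.raises(cp.ValidationError, match="bounds"):
            cp.extract_slice(s, "axis2", 99.0)


class TestSpectrumIO:
    def test_round_trip(self, single_gauss_spectrum, tmp_path):
        s, _ = single_gauss_spectrum
        prefix = str(tmp_path / "spec")
        cp.write_spectrum(s, prefix)
        back = cp.read_spectrum(prefix)
        np.testing.assert_allclose(back.intensity, s.intensity, rtol=1e-7)
        assert back.axis1 == s.axis1
        assert back.axis2 == s.axis2
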