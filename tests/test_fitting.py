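"""Mixture fitting: recovery, model selection, diagonal pairing, masking."""

import math

import numpy as np
import pytest

import coilpeaks as cp
from coilpeaks.fitting import FitConstraints, fit_mixture


def _axes(lo1=44.0, hi1=62.0, lo2=9.0, hi2=28.0, label2="13C-CB"):
    return (
        cp.Axis.from_range("13C-CA", lo1, hi1, 0.1),
        cp.Axis.from_range(label2, lo2, hi2, 0.1),
    )


def _synthetic(components, noise_sd=0.0, seed=0, axes=None):
    spec = cp.SyntheticSpec(
        components=[cp.ComponentSpec(c, f, p) for c, f, p in components],
        noise_sd=noise_sd,
        seed=seed,
    )
    a1, a2 = axes or _axes()
    return cp.simulate_crosspeak(spec, a1, a2)


class TestFitMixture:
    def test_single_gaussian_self_recovery(self):
        s, _ = _synthetic([((53.0, 18.5), (3.0, 3.0), 1.0)])
        fit = fit_mixture(s, ((44, 62), (9, 28)), k=1, seed=0)
        assert fit.converged
        assert fit.fractions[0] == pytest.approx(1.0)
        assert fit.components[0].center[0] == pytest.approx(53.0, abs=0.05)
        assert fit.components[0].center[1] == pytest.approx(18.5, abs=0.05)
        assert fit.components[0].fwhm[0] == pytest.approx(3.0, abs=0.05)

    def test_two_equal_resolved_gaussians_recover_half_half(self):
        # symmetric construction: equal fractions, separated by 2x FWHM
        s, _ = _synthetic([((50.0, 18.0), (2.0, 2.0), 0.5), ((54.0, 18.0), (2.0, 2.0), 0.5)])
        fit = fit_mixture(s, ((44, 62), (9, 28)), k=2, seed=0)
        assert sorted(fit.fractions) == pytest.approx([0.5, 0.5], abs=0.02)

    def test_three_component_fibril_recovery_at_snr50(self):
        comps = [
            ((55.1, 18.5), (3.2, 3.2), 0.28),
            ((52.3, 18.9), (3.2, 3.2), 0.34),
            ((50.8, 23.3), (3.2, 3.2), 0.38),
        ]
        s, truth = _synthetic(comps, noise_sd=0.02, seed=3)
        cons = FitConstraints(initial_guesses=tuple(c for c, _, _ in comps))
        fit = fit_mixture(s, ((44, 62), (9, 28)), k=3, constraints=cons, seed=0)
        assert fit.converged
        for (center, _, frac), got_c, got_p in zip(comps, fit.components, fit.fractions):
            assert got_p == pytest.approx(frac, abs=0.03)
            assert got_c.center[0] == pytest.approx(center[0], abs=0.2)

    def test_fractions_sum_to_one(self):
        s, _ = _synthetic([((53.0, 18.0), (3.0, 3.0), 0.7), ((56.0, 22.0), (2.0, 2.0), 0.3)])
        fit = fit_mixture(s, ((44, 62), (9, 28)), k=2, seed=1)
        assert fit.fractions.sum() == pytest.approx(1.0, abs=1e-6)

    def test_empty_roi_rejected(self):
        s, _ = _synthetic([((53.0, 18.5), (3.0, 3.0), 1.0)])
        with pytest.raises(cp.DegenerateInputError):
            fit_mixture(s, ((44.0, 44.2), (9.0, 9.2)), k=1)

    def test_k_outside_range_rejected(self):
        s, _ = _synthetic([((53.0, 18.5), (3.0, 3.0), 1.0)])
        with pytest.raises(cp.ValidationError):
            fit_mixture(s, ((44, 62), (9, 28)), k=5)

    def test_analytic_integral_matches_pixel_sum(self):
        # oracle equivalence on a 0.1 ppm grid, wide margins
        rng = np.random.default_rng(42)
        a1, a2 = _axes(30.0, 80.0, -10.0, 45.0)
        g1, g2 = np.meshgrid(a1.ppm(), a2.ppm())
        for _ in range(10):
            comp = cp.GaussianComponent(
                center=(rng.uniform(45, 65), rng.uniform(5, 30)),
                fwhm=(rng.uniform(1.0, 5.0), rng.uniform(1.0, 5.0)),
                amplitude=rng.uniform(0.5, 5.0),
            )
            numeric = comp.evaluate(g1, g2).sum() * 0.01
            assert numeric == pytest.approx(comp.integral, rel=5e-3)

    def test_median_recovery_over_seeds(self):
        # k=2, separation 1.5x FWHM, SNR 20: median |fraction error| <= 2 pp
        comps = [((52.0, 18.0), (2.4, 2.4), 0.6), ((55.6, 18.0), (2.4, 2.4), 0.4)]
        frac_errors, center_errors = [], []
        for seed in range(12):
            s, _ = _synthetic(comps, noise_sd=0.05, seed=seed)
            cons = FitConstraints(initial_guesses=((52.0, 18.0), (55.6, 18.0)), n_starts=0)
            fit = fit_mixture(s, ((44, 62), (9, 28)), k=2, constraints=cons, seed=seed)
            frac_errors.append(abs(fit.fractions[0] - 0.6))
            center_errors.append(abs(fit.components[0].center[0] - 52.0))
        assert np.median(frac_errors) <= 0.02
        assert np.median(center_errors) <= 0.2


class TestSelectK:
    def test_single_gaussian_selects_one(self):
        s, _ = _synthetic([((53.0, 18.5), (3.0, 3.0), 1.0)], noise_sd=0.01, seed=1)
        k, summaries = cp.select_k(s, ((44, 62), (9, 28)), seed=0)
        assert k == 1
        assert set(summaries) == {1, 2, 3, 4}

    def test_three_separated_gaussians_select_three(self):
        comps = [
            ((48.0, 13.0), (2.0, 2.0), 0.4),
            ((53.0, 18.5), (2.0, 2.0), 0.35),
            ((58.0, 24.0), (2.0, 2.0), 0.25),
        ]
        s, _ = _synthetic(comps, noise_sd=0.02, seed=5)
        k, _ = cp.select_k(s, ((44, 62), (9, 28)), seed=0)
        assert k == 3

    def test_flat_noise_flagged_degenerate(self):
        a1, a2 = _axes()
        rng = np.random.default_rng(7)
        flat = cp.Spectrum2D(a1, a2, rng.normal(0, 1.0, (a2.n_points, a1.n_points)))
        k, info = cp.select_k(flat, ((44, 62), (9, 28)), seed=0)
        assert k == 0
        assert info["degenerate"]


class TestDiagonalPair:
    def _mirrored(self, noise_sd, seed):
        axes = (
            cp.Axis.from_range("13C", 40.0, 66.0, 0.1),
            cp.Axis.from_range("13C", 40.0, 66.0, 0.1),
        )
        region = cp.SyntheticSpec(
            components=[
                cp.ComponentSpec((55.0, 44.0), (3.0, 3.0), 0.67),
                cp.ComponentSpec((52.2, 46.5), (3.0, 3.0), 0.33),
            ],
        )
        spectrum, truth = cp.simulate_full_spectrum([region], axes, seed=seed, noise_sd=noise_sd)
        return spectrum

    def test_symmetric_noiseless_sd_zero(self):
        s = self._mirrored(0.0, 0)
        np.testing.assert_allclose(s.intensity, s.intensity.T, atol=1e-12)
        cons = FitConstraints(initial_guesses=((55.0, 44.0), (52.2, 46.5)), n_starts=0)
        res = cp.fit_diagonal_pair(
            s, ((48, 62), (40, 52)), ((40, 52), (48, 62)), k=2, constraints=cons, seed=0
        )
        for m in res.matched:
            pa = res.fit_above.fractions[res.fit_above.components.index(m.above)]
            assert m.population_sd == pytest.approx(0.0, abs=1e-6)
            assert m.population_mean == pytest.approx(pa, abs=1e-6)

    def test_sd_formula_two_values(self):
        # sd of two values a, b is |a-b|/sqrt(2)
        a, b = 0.40, 0.36
        assert abs(a - b) / math.sqrt(2) == pytest.approx(0.0283, abs=1e-4)
        s = self._mirrored(0.03, 11)
        cons = FitConstraints(initial_guesses=((55.0, 44.0), (52.2, 46.5)), n_starts=0)
        res = cp.fit_diagonal_pair(
            s, ((48, 62), (40, 52)), ((40, 52), (48, 62)), k=2, constraints=cons, seed=0
        )
        for m in res.matched:
            pa = res.fit_above.fractions[res.fit_above.components.index(m.above)]
            pb = res.fit_below.fractions[res.fit_below.components.index(m.below)]
            assert m.population_sd == pytest.approx(abs(pa - pb) / math.sqrt(2), abs=1e-9)
            assert m.population_mean == pytest.approx((pa + pb) / 2, abs=1e-9)

    def test_same_k_above_and_below(self):
        s = self._mirrored(0.02, 3)
        cons = FitConstraints(initial_guesses=((55.0, 44.0), (52.2, 46.5)), n_starts=0)
        res = cp.fit_diagonal_pair(
            s, ((48, 62), (40, 52)), ((40, 52), (48, 62)), k=2, constraints=cons, seed=0
        )
        assert res.fit_above.k_selected == res.fit_below.k_selected == 2
        assert len(res.matched) == 2


class TestMaskDiagonal:
    def _homonuclear(self, comps):
        axes = (
            cp.Axis.from_range("13C", 40.0, 60.0, 0.1),
            cp.Axis.from_range("13C", 40.0, 60.0, 0.1),
        )
        spec = cp.SyntheticSpec(components=[cp.ComponentSpec(c, f, p) for c, f, p in comps])
        s, _ = cp.simulate_crosspeak(spec, *axes)
        return s

    def test_zero_separation_leaves_spectrum_unchanged(self):
        s = self._homonuclear([((50.0, 50.0), (2.0, 2.0), 1.0)])
        masked = cp.mask_diagonal(s, 0.0)
        assert np.all(masked.weights == 1.0)
        np.testing.assert_allclose(masked.intensity, s.intensity)

    def test_on_diagonal_gaussian_mostly_masked(self):
        # band-integral closed form: band +/-2 ppm around the diagonal holds
        # most of a FWHM-2 Gaussian centred on it
        s = self._homonuclear([((50.0, 50.0), (2.0, 2.0), 1.0)])
        masked = cp.mask_diagonal(s, 2.0)
        kept = (masked.intensity * masked.weights).sum() / s.intensity.sum()
        assert 1.0 - kept > 0.5

    def test_far_off_diagonal_gaussian_nearly_untouched(self):
        s = self._homonuclear([((47.0, 53.0), (2.0, 2.0), 1.0)])
        masked = cp.mask_diagonal(s, 2.0)
        kept = (masked.intensity * masked.weights).sum() / s.intensity.sum()
        assert 1.0 - kept < 0.01

    def test_heteronuclear_axes_rejected(self):
        a1 = cp.Axis.from_range("13C-CA", 40.0, 60.0, 0.1)
        a2 = cp.Axis.from_range("15N", 100.0, 130.0, 0.1)
        s = cp.Spectrum2D(a1, a2, np.zeros((a2.n_points, a1.n_points)))
        with pytest.raises(cp.ValidationError):
            cp.mask_diagonal(s, 2.0)
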