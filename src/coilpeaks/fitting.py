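"""Constrained 2D Gaussian-mixture decomposition of cross-peaks.

A cross-peak region is modelled as a sum of 1-4 axis-aligned 2D Gaussians,
each parameterized by (center1, center2, fwhm1, fwhm2, amplitude).  Centers
are bounded to a small excursion around their initial guesses ("constrained
peak motion"), widths to a physical range.  Fractional populations come from
the analytic component integrals

    integral = amplitude * 2 pi sigma1 sigma2,   sigma = fwhm / (2 sqrt(2 ln 2))

normalized over components.  Peaks above and below the homonuclear diagonal
are fit independently with the same component count; matched components give
population mean +/- SD across the two fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, optimize

from .errors import (
    DegenerateInputError,
    MatchingError,
    ValidationError,
)
from .spectrum import SIGMA_PER_FWHM, Spectrum2D

GAUSS2D_INTEGRAL_PER_AMPLITUDE = 2.0 * math.pi * SIGMA_PER_FWHM**2  # x fwhm1 x fwhm2


@dataclass(frozen=True)
class GaussianComponent:
    """One axis-aligned 2D Gaussian line."""

    center: tuple[float, float]
    fwhm: tuple[float, float]
    amplitude: float

    def __post_init__(self):
        if not all(f > 0 for f in self.fwhm):
            raise ValidationError("component FWHM must be > 0 in both dimensions")

    @property
    def integral(self) -> float:
        """Analytic volume: amplitude * 2 pi sigma1 sigma2."""
        return self.amplitude * GAUSS2D_INTEGRAL_PER_AMPLITUDE * self.fwhm[0] * self.fwhm[1]

    def evaluate(self, ppm1, ppm2):
        s1 = self.fwhm[0] * SIGMA_PER_FWHM
        s2 = self.fwhm[1] * SIGMA_PER_FWHM
        return self.amplitude * np.exp(
            -((ppm1 - self.center[0]) ** 2) / (2 * s1**2)
            - ((ppm2 - self.center[1]) ** 2) / (2 * s2**2)
        )


@dataclass(frozen=True)
class FitConstraints:
    """Bounds applied to every mixture fit.

    center_bound_ppm: maximum center excursion from the initial guess.
    fwhm_bounds_ppm: admissible linewidth range.
    initial_guesses: optional list of (ppm1, ppm2) centers; when given, its
      length fixes how many of the k components are seeded from it.
    n_starts: seeded multistart count beyond the deterministic first start.
    """

    k_range: tuple[int, int] = (1, 4)
    center_bound_ppm: float = 1.0
    fwhm_bounds_ppm: tuple[float, float] = (0.5, 8.0)
    initial_guesses: tuple[tuple[float, float], ...] | None = None
    n_starts: int = 3

    def __post_init__(self):
        if not (1 <= self.k_range[0] <= self.k_range[1] <= 4):
            raise ValidationError("k_range must lie within [1, 4] and be ordered")
        if self.center_bound_ppm <= 0:
            raise ValidationError("center_bound_ppm must be > 0")
        lo, hi = self.fwhm_bounds_ppm
        if not 0 < lo < hi:
            raise ValidationError("fwhm_bounds_ppm must be positive and ordered")


@dataclass
class MixtureFit:
    """Result of one constrained mixture fit on one ROI."""

    components: list[GaussianComponent]
    fractions: np.ndarray
    residual_norm: float
    k_selected: int
    converged: bool
    roi: tuple = ()
    n_pixels: int = 0

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)

    def sorted_by_fraction(self) -> "MixtureFit":
        order = np.argsort(self.fractions)[::-1]
        return replace(
            self,
            components=[self.components[i] for i in order],
            fractions=self.fractions[order],
        )


@dataclass
class MatchedComponent:
    """One component matched across the diagonal."""

    above: GaussianComponent
    below: GaussianComponent
    population_mean: float
    population_sd: float


@dataclass
class DiagonalPairResult:
    fit_above: MixtureFit
    fit_below: MixtureFit
    matched: list[MatchedComponent]


def estimate_noise(spectrum: Spectrum2D, border: int = 5) -> float:
    """Noise from the median absolute deviation of border pixels (SNR reporting only)."""
    z = spectrum.intensity
    edge = np.concatenate(
        [z[:border, :].ravel(), z[-border:, :].ravel(), z[:, :border].ravel(), z[:, -border:].ravel()]
    )
    return float(1.4826 * np.median(np.abs(edge - np.median(edge))))


def _roi_arrays(spectrum: Spectrum2D, roi):
    si, sj = spectrum.roi_slices(roi)
    z = spectrum.intensity[si, sj]
    p1 = spectrum.axis1.ppm()[sj]
    p2 = spectrum.axis2.ppm()[si]
    g1, g2 = np.meshgrid(p1, p2)
    w = None
    if spectrum.weights is not None:
        w = spectrum.weights[si, sj]
    return g1, g2, z, w


def _default_initial_centers(g1, g2, z, k, smooth_pixels=3.0):
    """Top-k local maxima of the smoothed ROI, strongest first."""
    zs = ndimage.gaussian_filter(z, smooth_pixels)
    local_max = (ndimage.maximum_filter(zs, size=5) == zs) & (zs > 0.05 * zs.max())
    ii, jj = np.nonzero(local_max)
    order = np.argsort(zs[ii, jj])[::-1]
    centers = [(float(g1[i, j]), float(g2[i, j])) for i, j in zip(ii[order], jj[order])]
    while len(centers) < k:  # fall back to spreading around the global maximum
        i, j = np.unravel_index(np.argmax(zs), zs.shape)
        span1 = (g1.max() - g1.min()) or 1.0
        off = (len(centers) - k / 2) * 0.25 * span1
        centers.append((float(g1[i, j] + off), float(g2[i, j])))
    return centers[:k]


def _unpack(theta, k):
    out = []
    for m in range(k):
        c1, c2, f1, f2, a = theta[5 * m : 5 * m + 5]
        out.append(GaussianComponent(center=(c1, c2), fwhm=(f1, f2), amplitude=a))
    return out


def _model(theta, k, g1, g2):
    z = np.zeros_like(g1)
    for comp in _unpack(theta, k):
        z += comp.evaluate(g1, g2)
    return z


def fit_mixture(
    spectrum: Spectrum2D,
    roi,
    k: int,
    constraints: FitConstraints = FitConstraints(),
    seed: int = 0,
) -> MixtureFit:
    """Bounded nonlinear least-squares fit of k 2D Gaussians to one ROI.

    Initial centers come from ``constraints.initial_guesses`` when provided,
    else from local maxima of the smoothed ROI; a seeded multistart jitters
    the initial guesses and the best residual is kept.  A fit that never
    converges is returned flagged ``converged=False``, never silently.
    """
    if not constraints.k_range[0] <= k <= constraints.k_range[1]:
        raise ValidationError(f"k={k} outside k_range {constraints.k_range}")
    g1, g2, z, w = _roi_arrays(spectrum, roi)
    if z.size < 5 * k + 1:
        raise DegenerateInputError("ROI has fewer pixels than fit parameters")
    zmax = float(z.max())
    if zmax <= 0 or zmax < 1e-9 * float(spectrum.intensity.max()):
        raise DegenerateInputError("ROI contains no intensity above the numerical floor")
    sqrt_w = np.sqrt(w).ravel() if w is not None else None

    if constraints.initial_guesses is not None:
        guesses = [tuple(map(float, c)) for c in constraints.initial_guesses][:k]
        if len(guesses) < k:
            guesses += _default_initial_centers(g1, g2, z, k - len(guesses))
    else:
        guesses = _default_initial_centers(g1, g2, z, k)

    flo, fhi = constraints.fwhm_bounds_ppm
    fwhm0 = min(max(2.0, flo * 1.5), fhi * 0.9)
    rng = np.random.default_rng(seed)

    def residuals(theta):
        r = (_model(theta, k, g1, g2) - z).ravel()
        return r * sqrt_w if sqrt_w is not None else r

    best = None
    for start in range(1 + max(constraints.n_starts, 0)):
        theta0, lo, hi = [], [], []
        for cx, cy in guesses:
            jx = jy = 0.0
            if start > 0:
                jx, jy = rng.uniform(-0.5, 0.5, 2) * constraints.center_bound_ppm
            i0 = np.abs(g2[:, 0] - cy).argmin()
            j0 = np.abs(g1[0, :] - cx).argmin()
            a0 = max(float(z[i0, j0]), 0.05 * zmax) / k
            f0 = fwhm0 if start == 0 else float(rng.uniform(max(flo, 1.0), min(fhi, 5.0)))
            theta0 += [cx + jx, cy + jy, f0, f0, a0]
            lo += [cx - constraints.center_bound_ppm, cy - constraints.center_bound_ppm, flo, flo, 0.0]
            hi += [cx + constraints.center_bound_ppm, cy + constraints.center_bound_ppm, fhi, fhi, 10.0 * zmax]
        theta0 = np.clip(theta0, lo, hi)
        try:
            sol = optimize.least_squares(
                residuals, theta0, bounds=(lo, hi), method="trf", xtol=1e-10, ftol=1e-10
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None:
        return MixtureFit(
            components=[], fractions=np.array([]), residual_norm=math.inf,
            k_selected=k, converged=False, roi=tuple(map(tuple, roi)), n_pixels=z.size,
        )
    comps = _unpack(best.x, k)
    integrals = np.array([c.integral for c in comps])
    total = integrals.sum()
    fractions = integrals / total if total > 0 else np.full(k, 1.0 / k)
    return MixtureFit(
        components=comps,
        fractions=fractions,
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        k_selected=k,
        converged=bool(best.success),
        roi=tuple(map(tuple, roi)),
        n_pixels=z.size,
    )


def select_k(
    spectrum: Spectrum2D,
    roi,
    constraints: FitConstraints = FitConstraints(),
    criterion: str = "bic",
    seed: int = 0,
):
    """Pick the component count by BIC over ``constraints.k_range``.

    Returns (k_selected, summaries) where summaries maps k -> dict with the
    fit, residual norm and BIC so a user can override the choice.  A ROI with
    no signal above the estimated noise floor is flagged degenerate
    (k_selected = 0).
    """
    if criterion != "bic":
        raise ValidationError(f"unknown criterion {criterion!r}")
    g1, g2, z, _ = _roi_arrays(spectrum, roi)
    noise = estimate_noise(spectrum)
    # the expected maximum of ~1e4-1e5 pure-noise pixels is ~4.5 sigma, so a
    # real peak must clear a higher bar before k is meaningful
    if z.max() <= 6.0 * noise or z.max() <= 0:
        return 0, {"degenerate": True, "noise": noise, "max_intensity": float(z.max())}
    n = z.size
    summaries = {}
    best_k, best_bic = None, math.inf
    for k in range(constraints.k_range[0], constraints.k_range[1] + 1):
        fit = fit_mixture(spectrum, roi, k, constraints, seed=seed)
        rss = fit.residual_norm**2
        bic = n * math.log(max(rss / n, 1e-300)) + 5 * k * math.log(n)
        summaries[k] = {"fit": fit, "rss": rss, "bic": bic}
        if fit.converged and bic < best_bic:
            best_k, best_bic = k, bic
    if best_k is None:
        raise DegenerateInputError("no converged fit for any k in range")
    return best_k, summaries


def mask_diagonal(spectrum: Spectrum2D, min_separation_ppm: float) -> Spectrum2D:
    """Zero-weight pixels with |ppm1 - ppm2| below the separation (homonuclear only)."""
    fam1 = spectrum.axis1.label.split("-")[0]
    fam2 = spectrum.axis2.label.split("-")[0]
    if fam1 != fam2:
        raise ValidationError(
            f"axes {spectrum.axis1.label!r} / {spectrum.axis2.label!r} are "
            "heteronuclear; there is no diagonal to mask"
        )
    if min_separation_ppm < 0:
        raise ValidationError("min_separation_ppm must be >= 0")
    g1, g2 = np.meshgrid(spectrum.axis1.ppm(), spectrum.axis2.ppm())
    weights = (np.abs(g1 - g2) >= min_separation_ppm).astype(float)
    out = Spectrum2D(
        axis1=spectrum.axis1,
        axis2=spectrum.axis2,
        intensity=spectrum.intensity.copy(),
        metadata=dict(spectrum.metadata) | {"diagonal_masked_ppm": min_separation_ppm},
        weights=weights if spectrum.weights is None else weights * spectrum.weights,
    )
    return out


def fit_diagonal_pair(
    spectrum: Spectrum2D,
    roi_above,
    roi_below,
    k: int,
    constraints: FitConstraints = FitConstraints(),
    seed: int = 0,
    match_tolerance_ppm: float = 1.5,
) -> DiagonalPairResult:
    """Fit the same k above and below the diagonal; report mean +/- SD populations.

    ``roi_below`` must be the axis-swapped image of ``roi_above``.  Components
    are matched by proximity of the below-diagonal center's swap to the
    above-diagonal center; the two-fit sample SD is |p_above - p_below|/sqrt(2).
    """
    fit_above = fit_mixture(spectrum, roi_above, k, constraints, seed=seed)
    constraints_below = constraints
    if constraints.initial_guesses is not None:
        constraints_below = replace(
            constraints,
            initial_guesses=tuple((c2, c1) for c1, c2 in constraints.initial_guesses),
        )
    fit_below = fit_mixture(spectrum, roi_below, k, constraints_below, seed=seed + 1)

    matched: list[MatchedComponent] = []
    used = set()
    for ia, ca in enumerate(fit_above.components):
        best_j, best_d = None, math.inf
        for jb, cb in enumerate(fit_below.components):
            if jb in used:
                continue
            swapped = (cb.center[1], cb.center[0])
            d = math.hypot(swapped[0] - ca.center[0], swapped[1] - ca.center[1])
            if d < best_d:
                best_j, best_d = jb, d
        if best_j is None or best_d > match_tolerance_ppm:
            raise MatchingError(
                f"component {ia} at {ca.center} has no below-diagonal partner "
                f"within {match_tolerance_ppm} ppm (nearest at {best_d:.2f} ppm); "
                f"below centers: {[c.center for c in fit_below.components]}"
            )
        used.add(best_j)
        pa = float(fit_above.fractions[ia])
        pb = float(fit_below.fractions[best_j])
        matched.append(
            MatchedComponent(
                above=ca,
                below=fit_below.components[best_j],
                population_mean=(pa + pb) / 2.0,
                population_sd=abs(pa - pb) / math.sqrt(2.0),
            )
        )
    return DiagonalPairResult(fit_above=fit_above, fit_below=fit_below, matched=matched)


def fit_report_table(fit: MixtureFit, fraction_sds=None):
    """Tab-separated-style report rows mirroring a supplementary fit table."""
    import pandas as pd

    rows = []
    for i, (c, p) in enumerate(zip(fit.components, fit.fractions)):
        rows.append(
            {
                "component": i,
                "center1_ppm": c.center[0],
                "center2_ppm": c.center[1],
                "fwhm1_ppm": c.fwhm[0],
                "fwhm2_ppm": c.fwhm[1],
                "fraction": float(p),
                "fraction_sd": float(fraction_sds[i]) if fraction_sds is not None else np.nan,
                "class": "",
            }
        )
    return pd.DataFrame(rows)
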