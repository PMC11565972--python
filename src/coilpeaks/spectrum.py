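"""2D spectrum container, cross-peak synthesis, normalization and slicing.

The ``Spectrum2D`` grid is the unit every prediction, simulation and fitting
operation works on.  Axes are stored ascending in ppm (descending display
order is a rendering concern).  Intensity is indexed ``[i2, i1]``: rows run
along axis2 (indirect), columns along axis1 (direct).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, ValidationError

SIGMA_PER_FWHM = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class Axis:
    """Uniform ppm axis: ppm(i) = start_ppm + i * step_ppm."""

    label: str
    start_ppm: float
    step_ppm: float
    n_points: int

    def __post_init__(self):
        if self.n_points < 2:
            raise ValidationError(f"axis {self.label!r}: need >= 2 points")
        if self.step_ppm == 0:
            raise ValidationError(f"axis {self.label!r}: step_ppm must be nonzero")

    def ppm(self) -> np.ndarray:
        return self.start_ppm + self.step_ppm * np.arange(self.n_points)

    @property
    def limits(self) -> tuple[float, float]:
        lo, hi = sorted((self.start_ppm, self.start_ppm + self.step_ppm * (self.n_points - 1)))
        return lo, hi

    def contains(self, ppm: float) -> bool:
        lo, hi = self.limits
        return lo <= ppm <= hi

    def index_of(self, ppm: float) -> int:
        """Nearest grid index for a ppm value."""
        return int(round((ppm - self.start_ppm) / self.step_ppm))

    @classmethod
    def from_range(cls, label: str, lo: float, hi: float, step: float = 0.1) -> "Axis":
        n = int(round((hi - lo) / step)) + 1
        return cls(label=label, start_ppm=lo, step_ppm=step, n_points=n)


@dataclass
class Spectrum2D:
    """Intensity grid over two ppm axes, with provenance metadata.

    ``weights`` (optional, same shape) down-weights pixels during fitting;
    ``mask_diagonal`` sets it.
    """

    axis1: Axis
    axis2: Axis
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (self.axis2.n_points, self.axis1.n_points):
            raise ValidationError(
                f"intensity shape {self.intensity.shape} does not match axes "
                f"({self.axis2.n_points}, {self.axis1.n_points})"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise ValidationError("intensity grid contains non-finite values")

    @property
    def pixel_area(self) -> float:
        return abs(self.axis1.step_ppm * self.axis2.step_ppm)

    def integral(self) -> float:
        """Riemann-sum integral over the grid (intensity x pixel area)."""
        return float(self.intensity.sum() * self.pixel_area)

    def roi_slices(self, roi) -> tuple[slice, slice]:
        """Index slices for a ((lo1, hi1), (lo2, hi2)) ppm window pair."""
        (lo1, hi1), (lo2, hi2) = roi
        p1, p2 = self.axis1.ppm(), self.axis2.ppm()
        j = np.where((p1 >= min(lo1, hi1)) & (p1 <= max(lo1, hi1)))[0]
        i = np.where((p2 >= min(lo2, hi2)) & (p2 <= max(lo2, hi2)))[0]
        if j.size == 0 or i.size == 0:
            raise DegenerateInputError(f"ROI {roi} selects no grid points")
        return slice(i[0], i[-1] + 1), slice(j[0], j[-1] + 1)

    def roi_integral(self, roi) -> float:
        si, sj = self.roi_slices(roi)
        return float(self.intensity[si, sj].sum() * self.pixel_area)

    def transpose(self) -> "Spectrum2D":
        return Spectrum2D(
            axis1=self.axis2,
            axis2=self.axis1,
            intensity=self.intensity.T.copy(),
            metadata=dict(self.metadata),
            weights=None if self.weights is None else self.weights.T.copy(),
        )

    def scaled(self, factor: float) -> "Spectrum2D":
        return replace(self, intensity=self.intensity * factor, metadata=dict(self.metadata))


@dataclass(frozen=True)
class BroadeningSpec:
    """Gaussian line broadening expressed as FWHM in ppm per dimension."""

    fwhm_ppm: tuple[float, float] = (1.5, 1.5)

    def __post_init__(self):
        if not all(f > 0 for f in self.fwhm_ppm):
            raise ValidationError("broadening FWHM must be > 0")


def build_crosspeak(
    shifts: np.ndarray,
    axis1: Axis,
    axis2: Axis,
    broadening: BroadeningSpec = BroadeningSpec(),
    on_out_of_grid: str = "error",
) -> Spectrum2D:
    """Bin per-conformer (ppm1, ppm2) pairs onto the grid and Gaussian-broaden.

    The total integral equals n_conformers x pixel area before any
    normalization (the smoothing kernel is unit-sum with reflecting borders
    avoided by using constant padding; mass at the very edge can leak, so
    axes should enclose the shifts with margin).
    """
    shifts = np.asarray(shifts, dtype=float)
    if shifts.ndim != 2 or shifts.shape[1] != 2 or shifts.shape[0] < 1:
        raise ValidationError("shifts must be an (n, 2) array with n >= 1")
    lo1, hi1 = axis1.limits
    lo2, hi2 = axis2.limits
    inside = (
        (shifts[:, 0] >= lo1) & (shifts[:, 0] <= hi1)
        & (shifts[:, 1] >= lo2) & (shifts[:, 1] <= hi2)
    )
    if not inside.all():
        n_out = int((~inside).sum())
        if on_out_of_grid == "error":
            raise ValidationError(
                f"{n_out} shift pair(s) fall outside the grid "
                f"[{lo1}, {hi1}] x [{lo2}, {hi2}]"
            )
        elif on_out_of_grid == "clip":
            warnings.warn(f"clipping {n_out} out-of-grid shift pair(s)", stacklevel=2)
            shifts = shifts.copy()
            shifts[:, 0] = np.clip(shifts[:, 0], lo1, hi1)
            shifts[:, 1] = np.clip(shifts[:, 1], lo2, hi2)
        else:
            raise ValidationError(f"on_out_of_grid must be 'error' or 'clip', got {on_out_of_grid!r}")

    # Histogram with bins centred on the grid points.
    e1 = axis1.start_ppm + axis1.step_ppm * (np.arange(axis1.n_points + 1) - 0.5)
    e2 = axis2.start_ppm + axis2.step_ppm * (np.arange(axis2.n_points + 1) - 0.5)
    if axis1.step_ppm < 0:
        e1 = e1[::-1]
    if axis2.step_ppm < 0:
        e2 = e2[::-1]
    counts, _, _ = np.histogram2d(shifts[:, 1], shifts[:, 0], bins=[np.sort(e2), np.sort(e1)])
    # histogram2d returns ascending-ppm order; flip to grid-index order if needed
    if axis1.step_ppm < 0:
        counts = counts[:, ::-1]
    if axis2.step_ppm < 0:
        counts = counts[::-1, :]
    sig2 = broadening.fwhm_ppm[1] * SIGMA_PER_FWHM / abs(axis2.step_ppm)
    sig1 = broadening.fwhm_ppm[0] * SIGMA_PER_FWHM / abs(axis1.step_ppm)
    smooth = ndimage.gaussian_filter(counts, sigma=(sig2, sig1), mode="constant", truncate=6.0)
    return Spectrum2D(
        axis1=axis1,
        axis2=axis2,
        intensity=smooth,
        metadata={
            "kind": "predicted_crosspeak",
            "n_conformers": int(shifts.shape[0]),
            "broadening_fwhm_ppm": list(broadening.fwhm_ppm),
        },
    )


def normalize_integral(spectrum: Spectrum2D) -> Spectrum2D:
    """Scale so the Riemann-sum integral over the grid equals 1."""
    total = spectrum.integral()
    if total == 0:
        raise DegenerateInputError("cannot normalize an all-zero spectrum")
    out = spectrum.scaled(1.0 / total)
    out.metadata["normalized"] = True
    return out


def match_intensity(reference: Spectrum2D, target: Spectrum2D, roi):
    """Scale ``target`` so its ROI integral matches the reference's.

    Returns (factor, scaled target) with factor = ref ROI integral / target
    ROI integral.
    """
    ref_int = reference.roi_integral(roi)
    tgt_int = target.roi_integral(roi)
    if ref_int <= 0:
        raise DegenerateInputError("reference ROI integral is not positive")
    if tgt_int == 0:
        raise DegenerateInputError("target ROI integral is zero; cannot match")
    factor = ref_int / tgt_int
    scaled = target.scaled(factor)
    scaled.metadata["intensity_match_factor"] = factor
    return factor, scaled


def extract_slice(spectrum: Spectrum2D, axis_choice: str, at_ppm: float, interpolate: bool = False):
    """1D profile through the spectrum at a fixed ppm on one axis.

    ``axis_choice`` names the axis held fixed ("axis1" or "axis2"); the
    returned (ppm, intensity) arrays run along the other axis, peak-normalized
    to unit maximum.  Nearest-row by default; linear interpolation between the
    two flanking rows when ``interpolate`` is set.
    """
    if axis_choice not in ("axis1", "axis2"):
        raise ValidationError("axis_choice must be 'axis1' or 'axis2'")
    fixed = spectrum.axis1 if axis_choice == "axis1" else spectrum.axis2
    if not fixed.contains(at_ppm):
        lo, hi = fixed.limits
        raise ValidationError(
            f"{at_ppm} ppm outside axis {fixed.label!r} bounds [{lo}, {hi}]"
        )
    frac = (at_ppm - fixed.start_ppm) / fixed.step_ppm
    if interpolate:
        i0 = int(np.floor(frac))
        i1 = min(i0 + 1, fixed.n_points - 1)
        t = frac - i0
        if axis_choice == "axis1":
            profile = (1 - t) * spectrum.intensity[:, i0] + t * spectrum.intensity[:, i1]
        else:
            profile = (1 - t) * spectrum.intensity[i0, :] + t * spectrum.intensity[i1, :]
    else:
        i = int(round(frac))
        profile = spectrum.intensity[:, i] if axis_choice == "axis1" else spectrum.intensity[i, :]
    other = spectrum.axis2 if axis_choice == "axis1" else spectrum.axis1
    peak = np.abs(profile).max()
    if peak == 0:
        raise DegenerateInputError("slice is identically zero; cannot peak-normalize")
    return other.ppm(), profile / peak


def write_spectrum(spectrum: Spectrum2D, path_prefix: str) -> tuple[str, str]:
    """Write the portable text format: <prefix>.txt matrix + <prefix>.json sidecar."""
    mat_path = f"{path_prefix}.txt"
    meta_path = f"{path_prefix}.json"
    np.savetxt(mat_path, spectrum.intensity, fmt="%.8e")
    meta = {
        "axis1": vars(spectrum.axis1) | {},
        "axis2": vars(spectrum.axis2) | {},
        "metadata": spectrum.metadata,
    }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1, default=str)
    return mat_path, meta_path


def read_spectrum(path_prefix: str) -> Spectrum2D:
    with open(f"{path_prefix}.json") as fh:
        meta = json.load(fh)
    intensity = np.loadtxt(f"{path_prefix}.txt", ndmin=2)
    return Spectrum2D(
        axis1=Axis(**meta["axis1"]),
        axis2=Axis(**meta["axis2"]),
        intensity=intensity,
        metadata=meta.get("metadata", {}),
    )
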