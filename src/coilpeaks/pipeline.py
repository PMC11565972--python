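"""End-to-end statistical-coil cross-peak prediction and decomposition.

The chain mirrors the frozen-state peak-shape analysis workflow: sample a
host–guest coil ensemble, predict the guest residue's 13C shifts, histogram
and broaden them into a 2D cross-peak, fit a constrained Gaussian mixture,
and classify the components into conformational classes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .classify import ClassifiedComponent, ClassWindows, classify_fit
from .fitting import FitConstraints, MixtureFit, fit_mixture
from .library import DihedralLibrary, build_host_guest, sample_ensemble
from .shifts import ShiftSurface, predict_ensemble_shifts
from .spectrum import Axis, BroadeningSpec, Spectrum2D, build_crosspeak, normalize_integral

DEFAULT_N_CONFORMERS = 10_000


@dataclass
class CoilDecomposition:
    """Everything one coil-prediction run produces."""

    guest: str
    atoms: tuple[str, str]
    spectrum: Spectrum2D
    fit: MixtureFit
    classified: list[ClassifiedComponent]

    def fractions_by_class(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for cc in self.classified:
            out[cc.label] = out.get(cc.label, 0.0) + cc.fraction
        return out


def coil_crosspeak_prediction(
    guest: str,
    atoms: tuple[str, str] = ("CA", "CB"),
    n: int = DEFAULT_N_CONFORMERS,
    seed: int = 0,
    host_length: int = 11,
    library: DihedralLibrary | None = None,
    surface: ShiftSurface | None = None,
    broadening: BroadeningSpec = BroadeningSpec(),
    pad_ppm: float = 8.0,
    step_ppm: float = 0.1,
) -> Spectrum2D:
    """Predicted, integral-normalized 2D cross-peak for one guest residue."""
    library = library if library is not None else DihedralLibrary.default()
    surface = surface if surface is not None else ShiftSurface.default(library)
    sequence = build_host_guest(guest, host_length, library)
    ensemble = sample_ensemble(library, sequence, n, seed)
    guest_index = host_length // 2
    shifts = predict_ensemble_shifts(surface, ensemble, guest_index, atoms)
    anchors = [surface.anchor_shifts(guest, a) for a in atoms]
    axis1 = Axis.from_range(
        f"13C-{atoms[0]}",
        min(anchors[0].values()) - pad_ppm, max(anchors[0].values()) + pad_ppm, step_ppm,
    )
    axis2 = Axis.from_range(
        f"13C-{atoms[1]}",
        min(anchors[1].values()) - pad_ppm, max(anchors[1].values()) + pad_ppm, step_ppm,
    )
    spec = build_crosspeak(shifts, axis1, axis2, broadening)
    spec.metadata.update({"guest": guest, "atoms": list(atoms), "seed": seed, "n": n})
    return normalize_integral(spec)


def coil_decomposition(
    guest: str,
    atoms: tuple[str, str] = ("CA", "CB"),
    k: int | None = None,
    n: int = DEFAULT_N_CONFORMERS,
    seed: int = 0,
    host_length: int = 11,
    library: DihedralLibrary | None = None,
    surface: ShiftSurface | None = None,
    windows: ClassWindows | None = None,
    constraints: FitConstraints | None = None,
) -> CoilDecomposition:
    """Full chain: sample, predict, broaden, fit, classify.

    ``k`` defaults to the number of basins of the guest residue (4) unless the
    guest's basin anchors are too close to resolve, in which case the caller
    should pass k explicitly (the glycine cross-peak is conventionally fit
    with a single Gaussian).  Initial guesses default to the surface anchors.
    """
    library = library if library is not None else DihedralLibrary.default()
    surface = surface if surface is not None else ShiftSurface.default(library)
    windows = windows if windows is not None else ClassWindows.default()
    spectrum = coil_crosspeak_prediction(
        guest, atoms, n=n, seed=seed, host_length=host_length,
        library=library, surface=surface,
    )
    anchors1 = surface.anchor_shifts(guest, atoms[0])
    anchors2 = surface.anchor_shifts(guest, atoms[1])
    basin_order = [b.label for b in library.basins(guest)]
    if k is None:
        k = len(basin_order)
    if constraints is None:
        if k == len(basin_order):
            guesses = tuple((anchors1[b], anchors2[b]) for b in basin_order)
        elif k == 1:
            weights = {b.label: b.weight for b in library.basins(guest)}
            c1 = sum(anchors1[b] * w for b, w in weights.items())
            c2 = sum(anchors2[b] * w for b, w in weights.items())
            guesses = ((c1, c2),)
        else:
            guesses = None
        constraints = FitConstraints(initial_guesses=guesses)
    roi = (spectrum.axis1.limits, spectrum.axis2.limits)
    fit = fit_mixture(spectrum, roi, k, constraints, seed=seed)
    classified = classify_fit(fit, windows, guest, atoms)
    return CoilDecomposition(
        guest=guest, atoms=atoms, spectrum=spectrum, fit=fit, classified=classified
    )
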