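"""Backbone-dihedral chemical-shift surface.

A smooth 360-degree-periodic map (phi, psi) -> 13C shift for each
(residue type, atom) pair.  The surface is anchored at the four Ramachandran
basin centroids: each basin carries an anchor shift plus a local slope term
describing how the shift drifts as the backbone moves within the basin, and
the four basin values are blended with normalized periodic-Gaussian kernel
weights centred on the basin centroids:

    shift(phi, psi) = sum_b w_b(phi, psi) * [ a_b + g_phi,b sin(dphi_b)
                                                  + g_psi,b sin(dpsi_b) ]
    w_b ∝ exp(-(dphi_b^2 + dpsi_b^2) / (2 kappa^2))

with dphi_b, dpsi_b the wrapped angular offsets from basin b's centroid and
kappa the kernel width.  At a basin centroid (well-separated basins) the
surface equals that basin's anchor; the slope terms have zero mean over a
symmetric basin density, so ensemble-average shifts per basin stay at the
anchors while within-basin dispersion is set by slope x angular spread.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import ConfigurationError, UnsupportedAtomError
from .library import DihedralLibrary, angular_difference

ATOMS = ("CA", "CB", "CO")


@dataclass(frozen=True)
class ShiftAnchor:
    """Anchor shift (ppm) of one (residue, atom) pair in one basin.

    slope_phi / slope_psi (ppm) scale the sin() of the angular offset from the
    basin centroid, i.e. the local dependence of the shift on the backbone.
    """

    residue_type: str
    atom: str
    basin: str
    shift: float
    slope_phi: float = 0.0
    slope_psi: float = 0.0

    def __post_init__(self):
        if self.atom not in ATOMS:
            raise ConfigurationError(f"unknown atom {self.atom!r}")
        if not 10.0 <= self.shift <= 190.0:
            raise ConfigurationError(
                f"{self.residue_type} {self.atom} {self.basin}: "
                f"shift {self.shift} ppm outside the plausible 13C range (10-190)"
            )


class ShiftSurface:
    """Kernel-blended anchor surface over the Ramachandran torus."""

    def __init__(
        self,
        anchors: list[ShiftAnchor],
        library: DihedralLibrary | None = None,
        kernel_width: float = 25.0,
    ):
        if kernel_width <= 0:
            raise ConfigurationError("kernel_width must be > 0")
        self.kernel_width = float(kernel_width)
        self.library = library if library is not None else DihedralLibrary.default()
        self._anchors: dict[tuple[str, str], dict[str, ShiftAnchor]] = {}
        for a in anchors:
            self._anchors.setdefault((a.residue_type, a.atom), {})[a.basin] = a
        for (res, atom), per_basin in self._anchors.items():
            expected = {b.label for b in self.library.basins(res)} if res in self.library else set()
            missing = expected - set(per_basin)
            if missing:
                raise ConfigurationError(
                    f"anchor set for ({res}, {atom}) missing basins: {sorted(missing)}"
                )

    def anchor_shifts(self, residue_type: str, atom: str) -> dict[str, float]:
        """Anchor ppm per basin label for one (residue, atom) pair."""
        per_basin = self._anchor_set(residue_type, atom)
        return {b: a.shift for b, a in per_basin.items()}

    def supports(self, residue_type: str, atom: str) -> bool:
        return (residue_type, atom) in self._anchors

    def _anchor_set(self, residue_type: str, atom: str) -> dict[str, ShiftAnchor]:
        try:
            return self._anchors[(residue_type, atom)]
        except KeyError:
            raise ConfigurationError(
                f"no shift anchors for residue {residue_type!r}, atom {atom!r}"
            ) from None

    def predict(self, residue_type: str, atom: str, phi, psi):
        """Predicted shift(s) in ppm; phi/psi may be scalars or arrays (degrees)."""
        per_basin = self._anchor_set(residue_type, atom)
        phi = np.asarray(phi, dtype=float)
        psi = np.asarray(psi, dtype=float)
        num = np.zeros(np.broadcast(phi, psi).shape)
        den = np.zeros_like(num)
        for basin in self.library.basins(residue_type):
            a = per_basin[basin.label]
            dphi = angular_difference(phi, basin.center[0])
            dpsi = angular_difference(psi, basin.center[1])
            w = np.exp(-(dphi**2 + dpsi**2) / (2.0 * self.kernel_width**2))
            value = (
                a.shift
                + a.slope_phi * np.sin(np.deg2rad(dphi))
                + a.slope_psi * np.sin(np.deg2rad(dpsi))
            )
            num += w * value
            den += w
        out = num / np.maximum(den, 1e-300)
        return float(out) if out.ndim == 0 else out

    @classmethod
    def from_dict(cls, payload: dict, library: DihedralLibrary | None = None) -> "ShiftSurface":
        anchors = [
            ShiftAnchor(
                residue_type=rec["residue"],
                atom=rec["atom"],
                basin=rec["basin"],
                shift=float(rec["shift"]),
                slope_phi=float(rec.get("slope_phi", 0.0)),
                slope_psi=float(rec.get("slope_psi", 0.0)),
            )
            for rec in payload["anchors"]
        ]
        return cls(anchors, library=library, kernel_width=float(payload.get("kernel_width", 25.0)))

    @classmethod
    def from_json(cls, path, library: DihedralLibrary | None = None) -> "ShiftSurface":
        with open(path) as fh:
            return cls.from_dict(json.load(fh), library=library)

    @classmethod
    def default(cls, library: DihedralLibrary | None = None) -> "ShiftSurface":
        """The packaged anchor table (calibrated with the packaged coil library)."""
        text = resources.files("coilpeaks.data").joinpath("shift_anchors.json").read_text()
        return cls.from_dict(json.loads(text), library=library)


def predict_shift(surface: ShiftSurface, residue_type: str, atom: str, phi, psi):
    return surface.predict(residue_type, atom, phi, psi)


def predict_ensemble_shifts(surface, ensemble, residue_index, atoms=("CA", "CB")):
    """Per-conformer shift tuples for one residue of an ensemble.

    Returns an (n_conformers, len(atoms)) array in conformer order.
    """
    if not 0 <= residue_index < len(ensemble.sequence):
        raise IndexError(
            f"residue_index {residue_index} out of range for sequence of "
            f"length {len(ensemble.sequence)}"
        )
    res = ensemble.sequence[residue_index]
    if res == "G" and "CB" in atoms:
        raise UnsupportedAtomError("glycine has no CB; requested atoms include CB")
    phi = ensemble.angles[:, residue_index, 0]
    psi = ensemble.angles[:, residue_index, 1]
    cols = [np.atleast_1d(surface.predict(res, atom, phi, psi)) for atom in atoms]
    return np.column_stack(cols) if cols else np.empty((ensemble.n_conformers, 0))
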