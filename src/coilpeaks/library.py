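"""Statistical-coil dihedral library and host–guest ensemble sampling.

A coil library describes, per residue type, a mixture of wrapped bivariate
Gaussian basins on the Ramachandran torus.  Ensembles of a poly-alanine
host–guest peptide are drawn from it residue-by-residue (no nearest-neighbour
coupling): each conformer's (phi, psi) for a residue is sampled independently
from that residue type's basin mixture.  Angles are IUPAC phi/psi in degrees,
stored in [-180, 180).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UnsupportedResidueError, ValidationError

BASIN_LABELS = ("alpha", "beta", "ppii_coil", "positive_phi")


def wrap_angle(a):
    """Wrap angle(s) in degrees into [-180, 180)."""
    return (np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0


def angular_difference(a, b):
    """Signed periodic difference a - b in degrees, in [-180, 180)."""
    return wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


@dataclass(frozen=True)
class BasinSpec:
    """One Ramachandran basin: a wrapped Gaussian with a mixture weight.

    label : conformational class, one of ``BASIN_LABELS``
    center : (phi0, psi0) in degrees, each in [-180, 180)
    spread : (s_phi, s_psi) periodic Gaussian widths in degrees, > 0
    weight : mixture fraction in [0, 1]
    """

    label: str
    center: tuple[float, float]
    spread: tuple[float, float]
    weight: float

    def __post_init__(self):
        if self.label not in BASIN_LABELS:
            raise ConfigurationError(f"unknown basin label {self.label!r}")
        if not all(-180.0 <= c < 180.0 for c in self.center):
            raise ConfigurationError(
                f"basin {self.label}: center {self.center} outside [-180, 180)"
            )
        if not all(s > 0 for s in self.spread):
            raise ConfigurationError(f"basin {self.label}: spreads must be > 0")
        if not 0.0 <= self.weight <= 1.0:
            raise ConfigurationError(f"basin {self.label}: weight {self.weight} not in [0, 1]")


class DihedralLibrary:
    """Per-residue-type collections of :class:`BasinSpec`.

    Basin weights within a residue type must sum to 1 (raw weights from a
    library file are normalized on load, so files may store relative weights
    such as printed percentages).
    """

    def __init__(self, entries: dict[str, Sequence[BasinSpec]]):
        self._entries: dict[str, tuple[BasinSpec, ...]] = {}
        for res, basins in entries.items():
            basins = tuple(basins)
            if not basins:
                raise ConfigurationError(f"residue {res!r}: empty basin list")
            total = sum(b.weight for b in basins)
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"residue {res!r}: basin weights sum to {total}, expected 1"
                )
            self._entries[res] = basins
        if "G" in self._entries:
            pos = [b for b in self._entries["G"] if b.label == "positive_phi"]
            if not pos or sum(b.weight for b in pos) <= 0:
                raise ConfigurationError("glycine entry must give positive_phi weight > 0")

    def __contains__(self, residue_type: str) -> bool:
        return residue_type in self._entries

    @property
    def residue_types(self) -> tuple[str, ...]:
        return tuple(self._entries)

    def basins(self, residue_type: str) -> tuple[BasinSpec, ...]:
        try:
            return self._entries[residue_type]
        except KeyError:
            raise UnsupportedResidueError(
                f"residue type {residue_type!r} not in coil library "
                f"(supported: {', '.join(self._entries)})"
            ) from None

    @classmethod
    def from_dict(cls, payload: dict) -> "DihedralLibrary":
        entries: dict[str, list[BasinSpec]] = {}
        for res, basins in payload.items():
            raw = [
                (
                    b["label"],
                    (float(b["center"][0]), float(b["center"][1])),
                    (float(b["spread"][0]), float(b["spread"][1])),
                    float(b["weight"]),
                )
                for b in basins
            ]
            total = sum(w for *_, w in raw)
            if total <= 0:
                raise ConfigurationError(f"residue {res!r}: nonpositive total weight")
            entries[res] = [
                BasinSpec(label, center, spread, w / total) for label, center, spread, w in raw
            ]
        return cls(entries)

    @classmethod
    def from_json(cls, path) -> "DihedralLibrary":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def default(cls) -> "DihedralLibrary":
        """The packaged coil library (calibrated against the shipped shift anchors)."""
        text = resources.files("coilpeaks.data").joinpath("coil_library.json").read_text()
        return cls.from_dict(json.loads(text))


@dataclass
class DihedralEnsemble:
    """A sampled conformational ensemble of one peptide.

    angles has shape (n_conformers, n_residues, 2) with (phi, psi) in degrees,
    wrapped to [-180, 180).  Bitwise reproducible for a fixed seed.
    """

    sequence: str
    angles: np.ndarray
    seed: int
    metadata: dict = field(default_factory=dict)

    @property
    def n_conformers(self) -> int:
        return int(self.angles.shape[0])

    def to_table(self) -> pd.DataFrame:
        n, length, _ = self.angles.shape
        conf = np.repeat(np.arange(n), length)
        resi = np.tile(np.arange(length), n)
        flat = self.angles.reshape(-1, 2)
        return pd.DataFrame(
            {
                "conformer_index": conf,
                "residue_index": resi,
                "residue_type": [self.sequence[i] for i in resi],
                "phi_deg": flat[:, 0],
                "psi_deg": flat[:, 1],
            }
        )

    def save_tsv(self, path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)


def build_host_guest(guest: str, host_length: int = 11, library: DihedralLibrary | None = None) -> str:
    """Poly-alanine host with ``guest`` at the central position.

    With even ``host_length`` the guest sits at index ``host_length // 2``.
    """
    if host_length < 1:
        raise ValidationError(f"host_length must be >= 1, got {host_length}")
    library = library if library is not None else DihedralLibrary.default()
    if guest not in library:
        raise UnsupportedResidueError(
            f"guest residue {guest!r} not in coil library "
            f"(supported: {', '.join(library.residue_types)})"
        )
    seq = ["A"] * host_length
    seq[host_length // 2] = guest
    return "".join(seq)


def sample_ensemble(
    library: DihedralLibrary, sequence: str, n: int, seed: int
) -> DihedralEnsemble:
    """Draw ``n`` conformers of ``sequence`` from the coil library.

    Each residue's (phi, psi) is drawn independently: a basin is chosen by its
    weight, then a wrapped bivariate normal around the basin center.
    """
    if n < 0:
        raise ValidationError(f"conformer count must be >= 0, got {n}")
    for res in set(sequence):
        if res not in library:
            raise UnsupportedResidueError(
                f"residue type {res!r} not in coil library "
                f"(supported: {', '.join(library.residue_types)})"
            )
    rng = np.random.default_rng(seed)
    length = len(sequence)
    angles = np.empty((n, length, 2), dtype=float)
    labels = np.empty((n, length), dtype=object)
    for i, res in enumerate(sequence):
        basins = library.basins(res)
        weights = np.array([b.weight for b in basins])
        choice = rng.choice(len(basins), size=n, p=weights / weights.sum())
        phi = np.empty(n)
        psi = np.empty(n)
        for j, b in enumerate(basins):
            mask = choice == j
            m = int(mask.sum())
            phi[mask] = rng.normal(b.center[0], b.spread[0], size=m)
            psi[mask] = rng.normal(b.center[1], b.spread[1], size=m)
            labels[mask, i] = b.label
        angles[:, i, 0] = wrap_angle(phi)
        angles[:, i, 1] = wrap_angle(psi)
    return DihedralEnsemble(
        sequence=sequence,
        angles=angles,
        seed=seed,
        metadata={"basin_labels": labels},
    )


def assign_basin(
    phi: float, psi: float, residue_type: str, library: DihedralLibrary | None = None
) -> str:
    """Label (phi, psi) with the nearest basin of the residue type.

    Nearest under periodic distance normalized per-axis by the basin spread.
    """
    if not (np.isfinite(phi) and np.isfinite(psi)):
        raise ValidationError("angles must be finite")
    library = library if library is not None else DihedralLibrary.default()
    best_label, best_d = None, np.inf
    for b in library.basins(residue_type):
        dphi = angular_difference(phi, b.center[0]) / b.spread[0]
        dpsi = angular_difference(psi, b.center[1]) / b.spread[1]
        d = float(dphi * dphi + dpsi * dpsi)
        if d < best_d:
            best_label, best_d = b.label, d
    return best_label


def basin_occupancy(
    ensemble: DihedralEnsemble,
    residue_index: int,
    library: DihedralLibrary | None = None,
    method: str = "generating",
) -> dict[str, float]:
    """Empirical fraction of conformers in each basin at one residue.

    method="generating" counts the basins the sampler actually drew (exact
    multinomial view, recorded at sampling time); method="assign" relabels
    angles geometrically with :func:`assign_basin`, which can differ slightly
    where basins overlap.
    """
    library = library if library is not None else DihedralLibrary.default()
    res = ensemble.sequence[residue_index]
    if method == "generating" and "basin_labels" in ensemble.metadata:
        labels = list(ensemble.metadata["basin_labels"][:, residue_index])
    else:
        labels = [
            assign_basin(phi, psi, res, library)
            for phi, psi in ensemble.angles[:, residue_index, :]
        ]
    n = max(len(labels), 1)
    return {lab: labels.count(lab) / n for lab in BASIN_LABELS}
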