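"""Conformational-class assignment of fitted components and population reports.

Reference windows are per-residue, per-atom (mean, SD) chemical shifts for the
alpha-helix, random-coil and beta-strand classes; a component is inside a
class when it falls within mean +/- 2 SD on both axes of the cross-peak.  The
positive-phi region is represented by an anchor point with a proximity radius
rather than a tabulated window.  Assignment is by minimal normalized distance

    d_class = max over atoms |center_atom - mean_class| / sd_class

(the positive-phi anchor enters the comparison with sd = radius / 2, so its
radius corresponds to the same 2-SD gate).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .fitting import DiagonalPairResult, GaussianComponent, MixtureFit

CLASS_LABELS = ("alpha", "coil", "beta", "positive_phi")


class ClassWindows:
    """Reference mean +/- SD shift windows plus positive-phi anchors."""

    def __init__(
        self,
        windows: dict[tuple[str, str], dict[str, tuple[float, float]]],
        positive_phi_anchors: dict[str, dict[str, float]] | None = None,
        extended_direction: dict[str, int] | None = None,
        positive_phi_radius_ppm: float = 1.5,
    ):
        for key, per_class in windows.items():
            for cls, (_, sd) in per_class.items():
                if sd <= 0:
                    raise ConfigurationError(f"window {key} {cls}: sd must be > 0")
        self._windows = windows
        self._pos_anchors = positive_phi_anchors or {}
        self.extended_direction = extended_direction or {"CA": -1, "CB": 1, "CO": -1}
        self.positive_phi_radius_ppm = positive_phi_radius_ppm

    def window(self, residue_type: str, atom: str, cls: str) -> tuple[float, float]:
        try:
            return self._windows[(residue_type, atom)][cls]
        except KeyError:
            raise ConfigurationError(
                f"no {cls} window for residue {residue_type!r}, atom {atom!r}"
            ) from None

    def has(self, residue_type: str, atom: str) -> bool:
        return (residue_type, atom) in self._windows

    def positive_phi_anchor(self, residue_type: str, atom: str) -> float | None:
        return self._pos_anchors.get(residue_type, {}).get(atom)

    @classmethod
    def from_dict(cls, payload: dict) -> "ClassWindows":
        windows: dict[tuple[str, str], dict[str, tuple[float, float]]] = {}
        for rec in payload["windows"]:
            key = (rec["residue"], rec["atom"])
            windows.setdefault(key, {})[rec["class"]] = (float(rec["mean"]), float(rec["sd"]))
        anchors = {
            rec["residue"]: {a: float(v) for a, v in rec["atoms"].items()}
            for rec in payload.get("positive_phi_anchors", [])
        }
        return cls(
            windows,
            positive_phi_anchors=anchors,
            extended_direction={k: int(v) for k, v in payload.get("extended_direction", {}).items()},
            positive_phi_radius_ppm=float(payload.get("positive_phi_radius_ppm", 1.5)),
        )

    @classmethod
    def from_json(cls, path) -> "ClassWindows":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def default(cls) -> "ClassWindows":
        text = resources.files("coilpeaks.data").joinpath("class_windows.json").read_text()
        return cls.from_dict(json.loads(text))


@dataclass
class ClassifiedComponent:
    component: GaussianComponent
    fraction: float
    fraction_sd: float
    label: str
    distances: dict[str, float] = field(default_factory=dict)
    within_2sd: bool = True
    extreme_beta: bool = False


def classify_component(
    component: GaussianComponent,
    windows: ClassWindows,
    residue_type: str,
    atoms: tuple[str, str],
    fraction: float = float("nan"),
    fraction_sd: float = 0.0,
) -> ClassifiedComponent:
    """Assign one fitted component to a conformational class.

    Intensity never enters the assignment (labels are scale-invariant); only
    the component center is compared with the windows.
    """
    for atom in atoms:
        if not windows.has(residue_type, atom):
            raise ConfigurationError(
                f"no class windows for residue {residue_type!r}, atom {atom!r}"
            )
    distances: dict[str, float] = {}
    for cls in ("alpha", "coil", "beta"):
        d = 0.0
        for atom, c in zip(atoms, component.center):
            mean, sd = windows.window(residue_type, atom, cls)
            d = max(d, abs(c - mean) / sd)
        distances[cls] = d
    pos_sd = windows.positive_phi_radius_ppm / 2.0
    pos_vals = [windows.positive_phi_anchor(residue_type, a) for a in atoms]
    if all(v is not None for v in pos_vals):
        distances["positive_phi"] = max(
            abs(c - v) / pos_sd for c, v in zip(component.center, pos_vals)
        )
    nearest = min(distances, key=distances.get)
    within = distances[nearest] <= 2.0

    # beyond the beta window edge in the extended-shift direction on any axis
    extreme = False
    for atom, c in zip(atoms, component.center):
        mean, sd = windows.window(residue_type, atom, "beta")
        direction = windows.extended_direction.get(atom, 0)
        if direction and direction * (c - mean) / sd > 2.0 and nearest == "beta":
            extreme = True

    if within or extreme:
        label = "beta" if extreme else nearest
    else:
        label = "unclassified"

    return ClassifiedComponent(
        component=component,
        fraction=fraction,
        fraction_sd=fraction_sd,
        label=label,
        distances=distances,
        within_2sd=within,
        extreme_beta=extreme,
    )


def classify_fit(
    fit: MixtureFit | DiagonalPairResult,
    windows: ClassWindows,
    residue_type: str,
    atoms: tuple[str, str],
) -> list[ClassifiedComponent]:
    """Classify every component of a fit (or of a diagonal pair's mean populations)."""
    if isinstance(fit, DiagonalPairResult):
        return [
            classify_component(
                m.above, windows, residue_type, atoms,
                fraction=m.population_mean, fraction_sd=m.population_sd,
            )
            for m in fit.matched
        ]
    return [
        classify_component(c, windows, residue_type, atoms, fraction=float(p))
        for c, p in zip(fit.components, fit.fractions)
    ]


def build_population_report(
    pair_results: list[MixtureFit | DiagonalPairResult],
    windows: ClassWindows,
    labels: list[str],
    residue_type: str,
    atoms: tuple[str, str],
) -> pd.DataFrame:
    """Per-condition, per-class population table (percent +/- quadrature SD).

    Rows: one per condition and occupied class; per-condition percentages sum
    to 100 (up to rounding) because fit fractions sum to 1.
    """
    if len(pair_results) < 1:
        raise ValidationError("need at least one condition")
    if len(labels) != len(pair_results):
        raise ValidationError("labels and pair_results length mismatch")
    if len(set(labels)) != len(labels):
        raise ValidationError(f"duplicate condition labels in {labels}")
    rows = []
    for label, result in zip(labels, pair_results):
        classified = classify_fit(result, windows, residue_type, atoms)
        per_class: dict[str, list[ClassifiedComponent]] = {}
        for cc in classified:
            per_class.setdefault(cc.label, []).append(cc)
        for cls, ccs in per_class.items():
            frac = sum(c.fraction for c in ccs)
            sd = math.sqrt(sum(c.fraction_sd**2 for c in ccs))
            rows.append(
                {
                    "condition": label,
                    "residue": residue_type,
                    "class": cls,
                    "percent": 100.0 * frac,
                    "percent_sd": 100.0 * sd,
                    "n_components": len(ccs),
                    "extreme_beta": any(c.extreme_beta for c in ccs),
                }
            )
    return pd.DataFrame(rows)
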