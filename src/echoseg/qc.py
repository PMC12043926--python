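"""Shape-descriptor quality control for candidate segmentations.

Every pipeline stage passes its candidate labels through :func:`qc_gate`,
which discards chambers of unreasonable size, eccentricity, solidity or
geometric chamber relationship.  The gate is a pure predicate: it returns a
pass flag plus *every* violated rule, and never mutates its inputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import skimage.measure
import yaml

from .datatypes import Chamber, ChamberMaskSet, View
from .errors import EmptyMaskError, UnconfiguredChamberError

__all__ = [
    "ShapeDescriptors",
    "ChamberRule",
    "QCConfig",
    "compute_shape_descriptors",
    "qc_gate",
]


@dataclass
class ShapeDescriptors:
    """Region descriptors of one chamber mask (physical units)."""

    area: float                  # cm^2
    eccentricity: float          # [0, 1)
    solidity: float              # (0, 1]
    centroid: tuple[float, float]  # (row mm, col mm)
    long_axis_length: float      # mm
    orientation: float           # degrees
    n_components: int


def compute_shape_descriptors(mask: np.ndarray, spacing: float) -> ShapeDescriptors:
    """Descriptors of the largest connected component of a binary mask.

    Area is pixel count x spacing^2 (all components); eccentricity and
    orientation come from the best-fit ellipse of the second moments,
    solidity is area / convex-hull area, and the long-axis length is the
    major-axis length of the fitted ellipse.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("cannot describe an empty mask")
    labels = skimage.measure.label(mask)
    props = skimage.measure.regionprops(labels)
    main = max(props, key=lambda p: p.area)
    return ShapeDescriptors(
        area=float(mask.sum()) * spacing**2 / 100.0,
        eccentricity=float(main.eccentricity),
        solidity=float(main.solidity),
        centroid=(float(main.centroid[0]) * spacing, float(main.centroid[1]) * spacing),
        long_axis_length=float(main.axis_major_length) * spacing,
        orientation=float(np.degrees(main.orientation)),
        n_components=len(props),
    )


@dataclass
class ChamberRule:
    """Per-chamber descriptor bounds (areas in cm^2)."""

    area_min: float
    area_max: float
    eccentricity_max: float = 0.95
    solidity_min: float = 0.7

    def __post_init__(self) -> None:
        if not (0 <= self.area_min < self.area_max):
            raise ValueError("area bounds must satisfy 0 <= min < max")


@dataclass
class QCConfig:
    """Per-view QC rules: descriptor bounds plus relational rules.

    Relational rules for apical views: ventricles must sit apex-ward (lower
    row index; the sector apex is at the top of the image) of their atria;
    the LV/LA area ratio must lie within ``lv_la_ratio``; all cavity masks
    must be pairwise disjoint.  Fragments: only the largest connected
    component per chamber is evaluated, but secondary fragments larger than
    ``fragment_fraction`` of it cause failure.
    """

    rules: dict[Chamber, ChamberRule]
    require_ordering: bool = True
    lv_la_ratio: tuple[float, float] = (0.3, 6.0)
    fragment_fraction: float = 0.10

    @classmethod
    def default(cls, view: View) -> "QCConfig":
        rules = {
            Chamber.LV: ChamberRule(5.0, 80.0),
            Chamber.LA: ChamberRule(3.0, 60.0),
            Chamber.RV: ChamberRule(4.0, 60.0),
            Chamber.RA: ChamberRule(3.0, 60.0),
            Chamber.LV_EPI: ChamberRule(8.0, 120.0),
        }
        return cls(rules=rules, require_ordering=view in (View.A2C, View.A4C))

    @classmethod
    def from_yaml(cls, path) -> "QCConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        rules = {
            Chamber(name): ChamberRule(**bounds)
            for name, bounds in raw.get("rules", {}).items()
        }
        kw = {k: raw[k] for k in ("require_ordering", "fragment_fraction") if k in raw}
        if "lv_la_ratio" in raw:
            kw["lv_la_ratio"] = tuple(raw["lv_la_ratio"])
        return cls(rules=rules, **kw)

    def to_yaml(self, path) -> None:
        raw = {
            "rules": {
                ch.value: {
                    "area_min": r.area_min,
                    "area_max": r.area_max,
                    "eccentricity_max": r.eccentricity_max,
                    "solidity_min": r.solidity_min,
                }
                for ch, r in self.rules.items()
            },
            "require_ordering": self.require_ordering,
            "lv_la_ratio": list(self.lv_la_ratio),
            "fragment_fraction": self.fragment_fraction,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh)


#: ventricle -> atrium pairs whose vertical ordering is checked
_ORDERING_PAIRS = ((Chamber.LV, Chamber.LA), (Chamber.RV, Chamber.RA))


def _main_component_area(mask: np.ndarray) -> tuple[float, float]:
    """(largest component area px, largest secondary fragment area px)."""
    labels = skimage.measure.label(mask)
    sizes = np.bincount(labels.ravel())[1:]
    if sizes.size == 0:
        return 0.0, 0.0
    main = float(sizes.max())
    rest = float(sorted(sizes)[-2]) if sizes.size > 1 else 0.0
    return main, rest


def qc_gate(masks: ChamberMaskSet, config: QCConfig) -> tuple[bool, list[str]]:
    """Gate a candidate mask set; returns (pass, every violated rule).

    A chamber present with no configured rule raises
    :class:`UnconfiguredChamberError`; an absent or empty chamber is simply
    skipped (absence is not a QC failure — the relational rules only apply
    to chambers that are present).
    """
    reasons: list[str] = []
    descriptors: dict[Chamber, ShapeDescriptors] = {}
    for chamber, mask in masks.masks.items():
        if not mask.any():
            continue
        if chamber not in config.rules:
            raise UnconfiguredChamberError(f"no QC rule for chamber {chamber.value}")
        rule = config.rules[chamber]
        desc = compute_shape_descriptors(mask, masks.pixel_spacing)
        descriptors[chamber] = desc
        if desc.area < rule.area_min:
            reasons.append(f"{chamber.value}: area below min")
        if desc.area > rule.area_max:
            reasons.append(f"{chamber.value}: area above max")
        if desc.eccentricity > rule.eccentricity_max:
            reasons.append(f"{chamber.value}: eccentricity above max")
        if desc.solidity < rule.solidity_min:
            reasons.append(f"{chamber.value}: solidity below min")
        main, fragment = _main_component_area(mask)
        if main > 0 and fragment / main > config.fragment_fraction:
            reasons.append(f"{chamber.value}: secondary fragment too large")

    if not masks.disjoint():
        reasons.append("relational: chamber masks overlap")

    if config.require_ordering:
        for vent, atr in _ORDERING_PAIRS:
            if vent in descriptors and atr in descriptors:
                # sector apex at top: ventricle centroid row must be smaller
                if descriptors[vent].centroid[0] >= descriptors[atr].centroid[0]:
                    reasons.append(
                        f"relational: {vent.value} not apex-ward of {atr.value} (ordering)"
                    )

    if Chamber.LV in descriptors and Chamber.LA in descriptors:
        ratio = descriptors[Chamber.LV].area / descriptors[Chamber.LA].area
        lo, hi = config.lv_la_ratio
        if not (lo <= ratio <= hi):
            reasons.append("relational: LV/LA area ratio out of bounds")

    return (len(reasons) == 0), reasons
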