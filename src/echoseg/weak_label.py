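"""Initial chamber labels with zero human input.

Classical computer vision plus clinical shape priors produce the pipeline's
starting labels: dark blood-pool extraction with depth-ordered LV/LA
assignment for the apical two-chamber view, Hough circle detection for the
short-axis view, edge-map filling, epicardial/endocardial label synthesis by
dilation/erosion, four-chamber relabelling of two-chamber predictions, and
the clinically guided RV-apex stretch.  Weak labels are expected to be
coarse; frames whose components fail the shape-prior gates are *rejected*
(returned as None), not errors — rejection is part of the recipe.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.ndimage
import skimage.feature
import skimage.filters
import skimage.measure
import skimage.morphology
import skimage.transform

from .datatypes import Chamber, ChamberMaskSet, Provenance, UltrasoundFrame, View
from .errors import (
    BadRangeError,
    DegenerateError,
    DegenerateMaskError,
    InvalidInputError,
    UnassignableError,
)
from .measure import mask_long_axis

__all__ = [
    "A2CWeakLabelConfig",
    "a2c_weak_label",
    "CircleHypothesis",
    "hough_circle_detect",
    "edge_to_filled_mask",
    "make_epi_endo_labels",
    "reassign_a4c_labels",
    "StretchResult",
    "stretch_rv_apex",
]


def _disk(radius_mm: float, spacing: float) -> np.ndarray:
    return skimage.morphology.disk(max(1, int(round(radius_mm / spacing))))


# --------------------------------------------------------------------------
# A2C: dark blood-pool extraction with shape priors
# --------------------------------------------------------------------------

@dataclass
class A2CWeakLabelConfig:
    """Shape-prior gates for the apical blood-pool recipe (all physical units)."""

    smooth_sigma_mm: float = 1.0
    opening_radius_mm: float = 2.0
    area_min_cm2: float = 5.0
    area_max_cm2: float = 80.0
    eccentricity_max: float = 0.95
    solidity_min: float = 0.7
    central_width_fraction: float = 0.6


def a2c_weak_label(
    frame: UltrasoundFrame, config: Optional[A2CWeakLabelConfig] = None
) -> Optional[ChamberMaskSet]:
    """Candidate LV and LA masks from one standardized A2C frame, or None.

    Recipe: Gaussian smoothing -> darkest-class threshold within the fan
    (3-class Otsu) -> morphological opening -> connected components ->
    shape-prior gates (area, eccentricity, solidity, centroid within the
    central fan width) -> the admissible component nearest the sector apex
    is LV, the one beyond the valve-plane gap is LA -> convex-hull
    smoothing.  Frames with fewer than two admissible components are
    rejected (None).
    """
    cfg = config or A2CWeakLabelConfig()
    img = frame.pixels
    spacing = frame.pixel_spacing
    bright = img > 0.02
    if not bright.any():
        return None
    fan = skimage.morphology.convex_hull_image(bright)
    if fan.sum() < 0.05 * img.size:
        return None
    smoothed = scipy.ndimage.gaussian_filter(img, sigma=cfg.smooth_sigma_mm / spacing)
    vals = smoothed[fan]
    try:
        thresholds = skimage.filters.threshold_multiotsu(vals, classes=3)
    except ValueError:  # fewer than 3 gray levels: no dark pools to find
        return None
    dark = fan & (smoothed < thresholds[0])
    dark = skimage.morphology.opening(dark, _disk(cfg.opening_radius_mm, spacing))
    labels = skimage.measure.label(dark)

    rows, cols = np.nonzero(fan)
    col_center = cols.mean()
    half_width = (cols.max() - cols.min() + 1) / 2.0

    admissible = []
    for prop in skimage.measure.regionprops(labels):
        area_cm2 = prop.area * spacing**2 / 100.0
        if not (cfg.area_min_cm2 <= area_cm2 <= cfg.area_max_cm2):
            continue
        if prop.eccentricity > cfg.eccentricity_max:
            continue
        if prop.solidity < cfg.solidity_min:
            continue
        if abs(prop.centroid[1] - col_center) > cfg.central_width_fraction * half_width:
            continue
        admissible.append(prop)
    if len(admissible) < 2:
        return None
    # the two largest pools; apex (top) proximal one is the ventricle
    admissible.sort(key=lambda p: p.area, reverse=True)
    lv_prop, la_prop = sorted(admissible[:2], key=lambda p: p.centroid[0])
    lv = skimage.morphology.convex_hull_image(labels == lv_prop.label)
    la = skimage.morphology.convex_hull_image(labels == la_prop.label)
    if (lv & la).any():
        return None
    return ChamberMaskSet(
        masks={Chamber.LV: lv, Chamber.LA: la},
        pixel_spacing=spacing,
        provenance=Provenance.WEAK,
        view=View.A2C,
    )


# --------------------------------------------------------------------------
# SAX: Hough circles
# --------------------------------------------------------------------------

@dataclass
class CircleHypothesis:
    """One Hough circle candidate (pixel units)."""

    center: tuple[float, float]  # (row, col)
    radius: float
    accumulator_score: float


def hough_circle_detect(
    frame: UltrasoundFrame,
    radius_range_mm: tuple[float, float] = (15.0, 45.0),
    max_candidates: int = 5,
    min_center_distance_mm: float = 20.0,
) -> list[CircleHypothesis]:
    """Gradient-based Hough circle candidates, sorted by accumulator score.

    Ties are broken by larger accumulator, then smaller radius.  An empty
    list is a valid result (e.g. a blank frame).
    """
    lo, hi = radius_range_mm
    if not (0 < lo < hi):
        raise BadRangeError("radius range must satisfy 0 < min < max")
    spacing = frame.pixel_spacing
    edges = skimage.feature.canny(frame.pixels, sigma=2.0)
    if not edges.any():
        return []
    radii = np.arange(
        max(2, int(round(lo / spacing))), int(round(hi / spacing)) + 1
    )
    accum = skimage.transform.hough_circle(edges, radii)
    min_dist = max(1, int(round(min_center_distance_mm / spacing)))
    # one best center per radius, then greedy suppression: two hypotheses
    # conflict only when centres are close AND radii are similar, so
    # concentric circles (endo + epi boundary) survive as distinct candidates
    candidates = []
    for i, r in enumerate(radii):
        flat = int(np.argmax(accum[i]))
        y, x = np.unravel_index(flat, accum[i].shape)
        candidates.append(
            CircleHypothesis(
                center=(float(y), float(x)),
                radius=float(r),
                accumulator_score=float(accum[i, y, x]),
            )
        )
    candidates.sort(key=lambda h: (-h.accumulator_score, h.radius))
    n_rows, n_cols = frame.shape
    hyps: list[CircleHypothesis] = []
    for h in candidates:
        if not (
            h.radius <= h.center[0] <= n_rows - 1 - h.radius
            and h.radius <= h.center[1] <= n_cols - 1 - h.radius
        ):
            continue
        conflict = any(
            math.hypot(h.center[0] - k.center[0], h.center[1] - k.center[1]) < min_dist
            and abs(h.radius - k.radius) <= max(2.0, 0.15 * k.radius)
            for k in hyps
        )
        if not conflict:
            hyps.append(h)
        if len(hyps) >= max_candidates:
            break
    return hyps


def circle_to_mask(hyp: CircleHypothesis, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a circle hypothesis as a filled disc mask."""
    rr, cc = np.mgrid[0: shape[0], 0: shape[1]]
    return (rr - hyp.center[0]) ** 2 + (cc - hyp.center[1]) ** 2 <= hyp.radius**2


# --------------------------------------------------------------------------
# edge maps -> filled labels; epi/endo synthesis
# --------------------------------------------------------------------------

def edge_to_filled_mask(
    edge_map: np.ndarray,
    threshold: float = 0.5,
    spacing: float = 0.5,
    closing_radius_mm: float = 3.0,
) -> np.ndarray:
    """Fill a thresholded edge-probability map into a region label.

    Edges above the threshold are morphologically closed; the largest
    *enclosed* region — a connected non-edge component that does not touch
    the image border — is returned together with its bounding edge pixels.
    A perfect circle outline therefore fills to a disc of the same radius;
    concentric outlines (endocardial plus epicardial boundary) resolve to
    the cavity, the largest fully enclosed region.  If no closed contour
    forms, the result is an all-False mask.
    """
    edges = np.asarray(edge_map, dtype=float) > threshold
    empty = np.zeros_like(edges, dtype=bool)
    if not edges.any():
        return empty
    # dilate rather than close: closing cannot bridge a gap in a thin
    # contour (the erosion half always reopens the bridge); the dilation is
    # undone at the end by growing the enclosed region back out
    selem = _disk(closing_radius_mm, spacing)
    closed = skimage.morphology.dilation(edges, selem)
    labels = skimage.measure.label(~closed, connectivity=1)
    border = np.unique(
        np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
    )
    sizes = np.bincount(labels.ravel())
    sizes[border] = 0
    sizes[0] = 0
    if sizes.max() == 0:
        return empty
    # prefer the largest simply-connected enclosed region: a chamber is a
    # blob, not an annulus (which arises between concentric boundaries)
    order = np.argsort(sizes)[::-1]
    interior = None
    for lab in order:
        if sizes[lab] == 0:
            break
        comp = labels == int(lab)
        if scipy.ndimage.binary_fill_holes(comp).sum() == comp.sum():
            interior = comp
            break
    if interior is None:
        interior = labels == int(order[0])
    # grow back to the contour line (undoing the bridging dilation; one
    # extra pixel spans the contour's own thickness)
    back = skimage.morphology.disk(selem.shape[0] // 2 + 1)
    return scipy.ndimage.binary_fill_holes(
        skimage.morphology.dilation(interior, back)
    )


def make_epi_endo_labels(
    cavity_mask: np.ndarray,
    spacing: float,
    wall_thickness_mm: float = 9.0,
    endo_margin_mm: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Epicardial / endocardial labels by dilating / eroding a cavity mask.

    ``endo ⊆ cavity ⊆ epi`` holds by construction.

    Raises
    ------
    DegenerateMaskError
        If the erosion annihilates the mask.
    """
    cavity = np.asarray(cavity_mask, dtype=bool)
    if not cavity.any():
        raise DegenerateMaskError("empty cavity mask")
    if wall_thickness_mm > 0:
        epi = skimage.morphology.dilation(cavity, _disk(wall_thickness_mm, spacing))
    else:
        epi = cavity.copy()
    if endo_margin_mm > 0:
        endo = skimage.morphology.erosion(cavity, _disk(endo_margin_mm, spacing))
    else:
        endo = cavity.copy()
    if not endo.any():
        raise DegenerateMaskError("erosion annihilated the cavity mask")
    return epi, endo


# --------------------------------------------------------------------------
# A4C: relabelling and RV apex stretch
# --------------------------------------------------------------------------

def reassign_a4c_labels(
    pred: ChamberMaskSet, orientation: str = "LV_on_image_right"
) -> ChamberMaskSet:
    """Turn two-chamber predictions on an A4C frame into four chamber labels.

    The input must contain exactly two ventricle-class components (under LV)
    and two atrium-class components (under LA).  Laterality is assigned by
    centroid column according to ``orientation``; each ventricle must lie
    apex-ward (smaller row) of the atrium on its side.

    Raises
    ------
    UnassignableError
        Component counts differ from (2, 2) or the vertical ordering fails.
    """
    if orientation not in ("LV_on_image_right", "LV_on_image_left"):
        raise ValueError("unknown orientation flag")
    comps: dict[str, list] = {}
    for key, cls in ((Chamber.LV, "ventricle"), (Chamber.LA, "atrium")):
        if key not in pred:
            raise UnassignableError(f"missing {cls} prediction")
        labels = skimage.measure.label(pred[key])
        props = skimage.measure.regionprops(labels)
        if len(props) != 2:
            raise UnassignableError(
                f"need exactly 2 {cls} components, found {len(props)}"
            )
        comps[cls] = [(p.centroid, labels == p.label) for p in props]

    def left_right(pair):
        a, b = sorted(pair, key=lambda item: item[0][1])
        return a, b  # (leftmost, rightmost)

    v_left, v_right = left_right(comps["ventricle"])
    a_left, a_right = left_right(comps["atrium"])
    if orientation == "LV_on_image_right":
        assign = {
            Chamber.LV: v_right, Chamber.RV: v_left,
            Chamber.LA: a_right, Chamber.RA: a_left,
        }
    else:
        assign = {
            Chamber.LV: v_left, Chamber.RV: v_right,
            Chamber.LA: a_left, Chamber.RA: a_right,
        }
    for vent, atr in ((Chamber.LV, Chamber.LA), (Chamber.RV, Chamber.RA)):
        if assign[vent][0][0] >= assign[atr][0][0]:
            raise UnassignableError(
                f"{vent.value} is not apex-ward of {atr.value}"
            )
    return ChamberMaskSet(
        masks={ch: m for ch, (_, m) in assign.items()},
        pixel_spacing=pred.pixel_spacing,
        provenance=pred.provenance,
        view=View.A4C,
    )


@dataclass
class StretchResult:
    """Outcome of the RV apex stretch."""

    mask: np.ndarray
    length_ratio: float
    reached_target: bool


def stretch_rv_apex(
    rv_mask: np.ndarray,
    lv_mask: np.ndarray,
    spacing: float,
    target_length_ratio: float = 0.9,
    cone_half_angle_deg: float = 25.0,
    max_iterations: int = 200,
) -> StretchResult:
    """Stretch the RV apex toward known RV/LV length correlations.

    The RV mask is grown by iterative single-pixel directional dilation
    restricted to a cone about its long axis pointing apex-ward (toward
    smaller row indices), until ``RV length / LV length`` reaches the target
    ratio, growth collides with the LV, or the iteration cap is hit.  The
    output stays a single connected component disjoint from the LV.

    Raises
    ------
    InvalidInputError
        If the input masks overlap or are empty.
    """
    rv = np.asarray(rv_mask, dtype=bool).copy()
    lv = np.asarray(lv_mask, dtype=bool)
    if not rv.any() or not lv.any():
        raise InvalidInputError("both masks must be nonempty")
    if (rv & lv).any():
        raise InvalidInputError("RV and LV masks overlap")

    lv_length, _, _ = mask_long_axis(lv, spacing)

    def rv_state(mask):
        rows, cols = np.nonzero(mask)
        if rows.size < 3:
            raise DegenerateError("RV mask too small for an axis")
        pts = np.column_stack([rows, cols]).astype(float)
        centroid = pts.mean(axis=0)
        cov = np.cov((pts - centroid).T)
        eigvals, eigvecs = np.linalg.eigh(cov)
        axis = eigvecs[:, int(np.argmax(eigvals))]
        if axis[0] > 0:  # point apex-ward (decreasing row)
            axis = -axis
        u = (pts - centroid) @ axis
        length = (float(u.max() - u.min()) + 1.0) * spacing
        return centroid, axis, length

    centroid, axis, rv_length = rv_state(rv)
    ratio = rv_length / lv_length
    if ratio >= target_length_ratio:
        return StretchResult(rv, ratio, True)

    cos_limit = math.cos(math.radians(cone_half_angle_deg))
    selem = skimage.morphology.disk(1)
    for _ in range(max_iterations):
        grown = skimage.morphology.dilation(rv, selem)
        cand = grown & ~rv & ~lv
        rows, cols = np.nonzero(cand)
        if rows.size:
            vec = np.column_stack([rows, cols]).astype(float) - centroid
            norm = np.linalg.norm(vec, axis=1)
            with np.errstate(invalid="ignore"):
                cosang = (vec @ axis) / np.maximum(norm, 1e-9)
            keep = cosang >= cos_limit
            rows, cols = rows[keep], cols[keep]
        if rows.size == 0:
            break
        rv[rows, cols] = True
        centroid, axis, rv_length = rv_state(rv)
        ratio = rv_length / lv_length
        if ratio >= target_length_ratio:
            break
    return StretchResult(rv, ratio, ratio >= target_length_ratio)
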