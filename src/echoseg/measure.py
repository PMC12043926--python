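"""Clinical chamber quantification from per-frame segmentations.

Implements the guideline measurement chain: per-frame area traces, sinusoid
fitting at the heart-rate frequency to pick the best video and its
end-diastolic (largest-area) / end-systolic (smallest-area) frames, the
method of discs (biplane and single-plane) for chamber volumes, the
area-length method for LV mass, LVEF = 100*(EDV-ESV)/EDV, and
normal/abnormal classification against a configurable guideline threshold
table (BSA-indexed where the guideline indexes).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .datatypes import Chamber, ChamberMaskSet, MeasurementSet
from .errors import (
    DegenerateError,
    EmptyTraceError,
    FitFailureError,
    InvalidGeometryError,
    InvertedPhasesError,
    ManualSelectionRequiredError,
    UnconfiguredMeasureError,
    UndersampledError,
)

__all__ = [
    "ClipMasks",
    "measure_study",
    "SinusoidFit",
    "area_trace",
    "fit_cardiac_sinusoid",
    "select_cycle_frames",
    "mask_long_axis",
    "method_of_discs",
    "lv_mass_area_length",
    "compute_lvef",
    "single_plane_ef_estimate",
    "MeasureThreshold",
    "default_threshold_table",
    "classify_measurements",
]


# --------------------------------------------------------------------------
# area traces and cardiac-cycle frame selection
# --------------------------------------------------------------------------

@dataclass
class SinusoidFit:
    """Least-squares sinusoid at the heart-rate frequency.

    ``offset + amplitude * sin(2*pi*f*t + phase)`` with ``f`` fixed at
    heart_rate / 60 Hz; ``r_squared`` is computed between the area trace and
    the fitted curve.
    """

    offset: float
    amplitude: float
    frequency: float
    phase: float
    r_squared: float


def area_trace(
    clip_masks: Sequence[Optional[ChamberMaskSet]], chamber: Chamber
) -> np.ndarray:
    """Per-frame chamber areas in cm^2; missing frames become NaN entries.

    A frame is missing when its mask set is None, lacks the chamber, or the
    chamber mask is empty.
    """
    if len(clip_masks) == 0:
        raise EmptyTraceError("no frames in clip")
    out = np.full(len(clip_masks), np.nan)
    for i, ms in enumerate(clip_masks):
        if ms is None or chamber not in ms:
            continue
        if ms[chamber].sum() == 0:
            continue
        out[i] = ms.area_cm2(chamber)
    return out


def _estimate_frequency(trace: np.ndarray, frame_rate: float) -> float:
    """Periodogram-peak frequency of the trace within 0.5-3 Hz."""
    good = np.isfinite(trace)
    t = np.arange(trace.size)[good] / frame_rate
    y = trace[good] - trace[good].mean()
    freqs = np.linspace(0.5, 3.0, 501)
    power = [
        np.abs(np.sum(y * np.exp(-2j * np.pi * f * t))) for f in freqs
    ]
    return float(freqs[int(np.argmax(power))])


def fit_cardiac_sinusoid(
    trace: Sequence[float],
    heart_rate: Optional[float],
    frame_rate: float,
) -> SinusoidFit:
    """Fit ``offset + amplitude*sin(2*pi*f*t + phase)`` with f fixed by heart rate.

    Linear least squares on the sin/cos basis at the fixed frequency.  When
    the heart rate is unknown, f is estimated from the periodogram peak of
    the trace within 0.5-3 Hz.

    Raises
    ------
    UndersampledError
        Fewer than 4 frames per cardiac cycle.
    FitFailureError
        Constant trace, or fitted amplitude indistinguishable from zero
        (relative amplitude < 1e-3) — the caller may fall back to manual
        frame choice.
    """
    trace = np.asarray(trace, dtype=float)
    good = np.isfinite(trace)
    if good.sum() < 4:
        raise FitFailureError("fewer than 4 usable frames")
    y = trace[good]
    if np.ptp(y) < 1e-12:
        raise FitFailureError("constant area trace")
    if heart_rate is None:
        f = _estimate_frequency(trace, frame_rate)
    else:
        f = heart_rate / 60.0
    if frame_rate < 4.0 * f:
        raise UndersampledError("fewer than 4 frames per cardiac cycle")
    t = np.arange(trace.size)[good] / frame_rate
    design = np.column_stack(
        [np.sin(2 * np.pi * f * t), np.cos(2 * np.pi * f * t), np.ones_like(t)]
    )
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    a, b, offset = coef
    amplitude = float(np.hypot(a, b))
    phase = float(math.atan2(b, a))
    fitted = design @ coef
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    scale = max(abs(float(offset)), float(np.abs(y).max()), 1e-12)
    if amplitude < 1e-3 * scale:
        raise FitFailureError("fitted amplitude is approximately zero")
    return SinusoidFit(float(offset), amplitude, f, phase, max(0.0, min(1.0, r2)))


def select_cycle_frames(
    study: Mapping[str, tuple[Optional[SinusoidFit], np.ndarray]],
) -> tuple[str, int, int]:
    """Pick the video with the best periodic fit and its ED / ES frames.

    ``study`` maps video_id -> (SinusoidFit or None for a failed fit, area
    trace).  The chosen video maximizes r^2; within it, end-diastole is the
    largest-area frame and end-systole the smallest (ties -> earliest frame).

    Raises
    ------
    ManualSelectionRequiredError
        If every video's sinusoid fit failed.
    """
    best_id, best_r2 = None, -1.0
    for vid in study:
        fit, _ = study[vid]
        if fit is not None and fit.r_squared > best_r2:
            best_id, best_r2 = vid, fit.r_squared
    if best_id is None:
        raise ManualSelectionRequiredError("no video has a successful sinusoid fit")
    trace = np.asarray(study[best_id][1], dtype=float)
    finite = np.where(np.isfinite(trace), trace, np.nan)
    ed = int(np.nanargmax(finite))
    es = int(np.nanargmin(finite))
    return best_id, ed, es


# --------------------------------------------------------------------------
# geometry: long axis and method of discs
# --------------------------------------------------------------------------

def mask_long_axis(mask: np.ndarray, spacing: float) -> tuple[float, np.ndarray, np.ndarray]:
    """Principal axis of a binary mask's second moments.

    Returns ``(length_mm, u, v)`` where ``u``/``v`` are the pixel coordinates
    (mm, centroid-centred) along the major and minor principal axes, and
    ``length_mm`` is the extent along the major axis plus one pixel (a
    rasterized segment of physical length L spans L/spacing - 1 pixel-centre
    gaps).
    """
    rows, cols = np.nonzero(np.asarray(mask, dtype=bool))
    if rows.size < 3:
        raise DegenerateError("mask too small for an axis")
    pts = np.column_stack([rows, cols]).astype(float) * spacing
    pts -= pts.mean(axis=0)
    cov = np.cov(pts.T)
    eigvals, eigvecs = np.linalg.eigh(cov)
    imajor = int(np.argmax(eigvals))
    major = eigvecs[:, imajor]
    minor = eigvecs[:, 1 - imajor]  # the other eigenvector (ties: circle)
    u = pts @ major
    v = pts @ minor
    length = float(u.max() - u.min()) + spacing
    if length <= 2 * spacing:
        raise DegenerateError("degenerate axis")
    return length, u, v


def _disc_diameters(mask: np.ndarray, spacing: float, n_discs: int) -> tuple[np.ndarray, float]:
    """Slab diameters of a mask in ``n_discs`` slabs along its long axis.

    The diameter of a slab is its area-average width (slab pixel area
    divided by slab height), which is robust to rasterization at the slab
    ends where the widest chord would overestimate.
    """
    length, u, v = mask_long_axis(mask, spacing)
    lo = u.min() - spacing / 2.0
    h = length / n_discs
    edges = lo + np.arange(n_discs + 1) * h
    diam = np.zeros(n_discs)
    for i in range(n_discs):
        sel = (u >= edges[i]) & (u < edges[i + 1])
        if sel.any():
            diam[i] = sel.sum() * spacing**2 / h
    return diam, length


def method_of_discs(
    masks: Mapping[str, ChamberMaskSet] | ChamberMaskSet,
    chamber: Chamber = Chamber.LV,
    n_discs: int = 20,
    mode: str = "biplane",
) -> float:
    """Chamber volume (mL) by the method of discs.

    Biplane: the chamber is sliced into ``n_discs`` slabs along each view's
    own long axis; with slab diameters ``a_i`` (first view) and ``b_i``
    (second view) and L the longer of the two lengths,
    ``V = (pi/4) * sum(a_i * b_i) * (L / n)``.  Single-plane uses ``a_i^2``.
    Output converts mm^3 to mL.

    Parameters
    ----------
    masks
        For biplane, a mapping of two view names (e.g. ``{"A4C": ..., "A2C":
        ...}``) to mask sets; for single-plane, one mask set (or a one-entry
        mapping).
    """
    if isinstance(masks, ChamberMaskSet):
        mask_sets = [masks]
    else:
        mask_sets = list(masks.values())
    if mode == "single":
        mask_sets = mask_sets[:1]
        if len(mask_sets) != 1:
            raise DegenerateError("single-plane mode needs one mask set")
    elif mode == "biplane":
        if len(mask_sets) != 2:
            raise DegenerateError("biplane mode needs exactly two views")
    else:
        raise ValueError(f"unknown mode {mode!r}")

    diams, lengths = [], []
    for ms in mask_sets:
        d, length = _disc_diameters(ms[chamber].astype(bool), ms.pixel_spacing, n_discs)
        diams.append(d)
        lengths.append(length)
    L = max(lengths)
    if mode == "single":
        volume_mm3 = math.pi / 4.0 * float(np.sum(diams[0] ** 2)) * (L / n_discs)
    else:
        volume_mm3 = math.pi / 4.0 * float(np.sum(diams[0] * diams[1])) * (L / n_discs)
    return volume_mm3 / 1000.0


# --------------------------------------------------------------------------
# LV mass, EF
# --------------------------------------------------------------------------

#: Myocardial density, g/cm^3.
MYOCARDIAL_DENSITY = 1.05


def lv_mass_area_length(epi_area: float, endo_area: float, lv_length: float) -> float:
    """LV mass (g) by the area-length method.

    With areas in cm^2 and length in cm, mean wall thickness
    ``t = sqrt(epi/pi) - sqrt(endo/pi)`` and

    ``mass = 1.05 * (5/6) * [epi_area*(L + t) - endo_area*L]``.
    """
    if endo_area <= 0 or lv_length <= 0:
        raise InvalidGeometryError("areas and length must be positive")
    if epi_area <= endo_area:
        raise InvalidGeometryError("epicardial area must exceed endocardial area")
    t = math.sqrt(epi_area / math.pi) - math.sqrt(endo_area / math.pi)
    return MYOCARDIAL_DENSITY * (5.0 / 6.0) * (
        epi_area * (lv_length + t) - endo_area * lv_length
    )


def compute_lvef(edv: float, esv: float) -> float:
    """LV ejection fraction in percent: 100 * (EDV - ESV) / EDV."""
    if edv <= 0:
        raise InvalidGeometryError("EDV must be positive")
    if esv < 0 or esv > edv:
        raise InvertedPhasesError("ESV must lie in [0, EDV]")
    return 100.0 * (edv - esv) / edv


def single_plane_ef_estimate(a4c_ed_mask: np.ndarray, a4c_es_mask: np.ndarray) -> float:
    """Single-view LVEF estimate from pixel areas and lengths.

    Single-plane area-length volume is proportional to A^2/L, so
    ``EF = 100 * (A_ed^2/L_ed - A_es^2/L_es) / (A_ed^2/L_ed)`` — a pure pixel
    ratio, invariant to the (unknown) pixel spacing.
    """
    def a2_over_l(mask: np.ndarray) -> float:
        area = float(np.asarray(mask, dtype=bool).sum())
        if area < 3:
            raise DegenerateError("mask too small")
        length, _, _ = mask_long_axis(mask, spacing=1.0)
        return area * area / length

    ved = a2_over_l(a4c_ed_mask)
    ves = a2_over_l(a4c_es_mask)
    return 100.0 * (ved - ves) / ved


# --------------------------------------------------------------------------
# normal / abnormal classification
# --------------------------------------------------------------------------

@dataclass
class MeasureThreshold:
    """One guideline threshold row.

    ``direction`` is 'abnormal_low' or 'abnormal_high'; the abnormal interval
    is closed at the boundary (a value exactly at the threshold is called
    abnormal).  ``threshold`` maps sex ('M'/'F') to the cut point; use the
    same value for both sexes when the guideline does not stratify.
    ``grades`` optionally maps sex to descending severity cut points
    ``(mild, moderate, severe)`` on the abnormal side.
    """

    direction: str
    threshold: dict[str, float]
    index_by_bsa: bool = False
    grades: dict[str, tuple[float, float, float]] = field(default_factory=dict)


def default_threshold_table() -> dict[str, MeasureThreshold]:
    """Chamber-quantification guideline thresholds (fully overridable config).

    Volumes and mass are BSA-indexed (mL/m^2, g/m^2); RV areas are indexed in
    cm^2/m^2; LVEF is not indexed.  LVEF and LV mass carry severity grades.
    """
    return {
        "lvef": MeasureThreshold(
            "abnormal_low",
            {"M": 52.0, "F": 54.0},
            grades={"M": (52.0, 41.0, 30.0), "F": (54.0, 41.0, 30.0)},
        ),
        "lvedv": MeasureThreshold("abnormal_high", {"M": 74.0, "F": 61.0}, index_by_bsa=True),
        "lvesv": MeasureThreshold("abnormal_high", {"M": 31.0, "F": 24.0}, index_by_bsa=True),
        "lv_mass": MeasureThreshold(
            "abnormal_high",
            {"M": 115.0, "F": 95.0},
            index_by_bsa=True,
            grades={"M": (115.0, 132.0, 149.0), "F": (95.0, 109.0, 122.0)},
        ),
        "la_volume": MeasureThreshold("abnormal_high", {"M": 34.0, "F": 34.0}, index_by_bsa=True),
        "ra_volume": MeasureThreshold("abnormal_high", {"M": 39.0, "F": 33.0}, index_by_bsa=True),
        "rveda": MeasureThreshold("abnormal_high", {"M": 12.6, "F": 11.5}, index_by_bsa=True),
        "rvesa": MeasureThreshold("abnormal_high", {"M": 7.4, "F": 6.4}, index_by_bsa=True),
    }


def _is_abnormal(value: float, thr: float, direction: str) -> bool:
    # abnormal side closed: boundary value counts as abnormal
    return value <= thr if direction == "abnormal_low" else value >= thr


def _grade(value: float, cuts: tuple[float, float, float], direction: str) -> str:
    mild, moderate, severe = cuts
    if direction == "abnormal_low":
        if value > mild:
            return "normal"
        if value > moderate:
            return "mild"
        if value > severe:
            return "moderate"
        return "severe"
    if value < mild:
        return "normal"
    if value < moderate:
        return "mild"
    if value < severe:
        return "moderate"
    return "severe"


def classify_measurements(
    ms: MeasurementSet,
    bsa: Optional[float],
    sex: str,
    thresholds: Optional[dict[str, MeasureThreshold]] = None,
) -> MeasurementSet:
    """Index by BSA where the guideline indexes and call normal/abnormal.

    LVEF and LV mass receive graded calls (normal/mild/moderate/severe) in
    addition to the binary call.

    Raises
    ------
    UnconfiguredMeasureError
        A measurement is present but has no threshold row, or requires BSA
        indexing and no (positive) BSA was supplied.
    """
    table = thresholds if thresholds is not None else default_threshold_table()
    sex = sex.upper()[0]
    if sex not in ("M", "F"):
        raise ValueError("sex must be 'M' or 'F'")
    for name, value in ms.as_dict().items():
        if value is None:
            continue
        if name not in table:
            raise UnconfiguredMeasureError(f"no threshold row for {name!r}")
        row = table[name]
        if row.index_by_bsa:
            if bsa is None or bsa <= 0:
                raise UnconfiguredMeasureError(
                    f"{name!r} requires BSA indexing but BSA is missing"
                )
            value = value / bsa
            ms.indexed[name] = value
        thr = row.threshold[sex]
        ms.category[name] = "abnormal" if _is_abnormal(value, thr, row.direction) else "normal"
        if row.grades:
            ms.grade[name] = _grade(value, row.grades[sex], row.direction)
    return ms


# --------------------------------------------------------------------------
# study-level measurement engine
# --------------------------------------------------------------------------

@dataclass
class ClipMasks:
    """Per-frame mask sets of one video, with its acquisition parameters."""

    video_id: str
    masks: list  # per-frame Optional[ChamberMaskSet]
    heart_rate: Optional[float]
    frame_rate: float

    @property
    def view(self):
        for ms in self.masks:
            if ms is not None:
                return ms.view
        return None


def _best_clip(
    clips: Sequence[ClipMasks], chamber: Chamber
) -> tuple[ClipMasks, np.ndarray, int, int]:
    """Best-periodic clip for a chamber, with its max/min-area frames."""
    fits: dict[str, tuple[Optional[SinusoidFit], np.ndarray]] = {}
    by_id = {}
    for clip in clips:
        trace = area_trace(clip.masks, chamber)
        try:
            fit = fit_cardiac_sinusoid(trace, clip.heart_rate, clip.frame_rate)
        except (FitFailureError, UndersampledError):
            fit = None
        fits[clip.video_id] = (fit, trace)
        by_id[clip.video_id] = clip
    vid, ed, es = select_cycle_frames(fits)
    return by_id[vid], fits[vid][1], ed, es


def measure_study(
    clips: Sequence[ClipMasks],
    bsa: Optional[float] = None,
    sex: str = "M",
    n_discs: int = 20,
    thresholds=None,
) -> MeasurementSet:
    """Guideline measurements for one study from segmented clips.

    LV volumes use the biplane method of discs when both apical views are
    present (ED/ES frames selected per view by the sinusoid-fit rule) and
    the single-plane method otherwise; LA volume follows the same
    convention at the atrial-maximum frame; RA volume is single-plane on the
    four-chamber view; RV areas are read at the ventricular ED/ES frames of
    the four-chamber view; LV mass comes from the short-axis
    epicardial/endocardial areas at ED with the LV length taken from an
    apical view.  Measures whose inputs are absent stay None.
    """
    from .datatypes import View

    by_view: dict[View, list[ClipMasks]] = {}
    for clip in clips:
        view = clip.view
        if view is not None:
            by_view.setdefault(view, []).append(clip)

    ms = MeasurementSet()
    apical_lv: dict[View, tuple[ChamberMaskSet, ChamberMaskSet]] = {}
    lv_length_mm: Optional[float] = None

    for view in (View.A4C, View.A2C):
        if view not in by_view:
            continue
        try:
            clip, _trace, ed, es = _best_clip(by_view[view], Chamber.LV)
        except ManualSelectionRequiredError:
            continue
        ed_masks, es_masks = clip.masks[ed], clip.masks[es]
        if ed_masks is None or es_masks is None:
            continue
        apical_lv[view] = (ed_masks, es_masks)
        if view is View.A4C:
            if Chamber.RV in ed_masks and ed_masks[Chamber.RV].any():
                ms.rveda = ed_masks.area_cm2(Chamber.RV)
            if Chamber.RV in es_masks and es_masks[Chamber.RV].any():
                ms.rvesa = es_masks.area_cm2(Chamber.RV)

    if apical_lv:
        try:
            if len(apical_lv) == 2:
                ed_pair = {v.value: m[0] for v, m in apical_lv.items()}
                es_pair = {v.value: m[1] for v, m in apical_lv.items()}
                ms.lvedv = method_of_discs(ed_pair, Chamber.LV, n_discs, "biplane")
                ms.lvesv = method_of_discs(es_pair, Chamber.LV, n_discs, "biplane")
            else:
                (ed_masks, es_masks), = apical_lv.values()
                ms.lvedv = method_of_discs(ed_masks, Chamber.LV, n_discs, "single")
                ms.lvesv = method_of_discs(es_masks, Chamber.LV, n_discs, "single")
            if ms.lvesv is not None and ms.lvedv is not None:
                ms.lvesv = min(ms.lvesv, ms.lvedv)
                ms.lvef = compute_lvef(ms.lvedv, ms.lvesv)
        except DegenerateError:
            pass
        some_view = next(iter(apical_lv))
        try:
            lv_length_mm, _, _ = mask_long_axis(
                apical_lv[some_view][0][Chamber.LV],
                apical_lv[some_view][0].pixel_spacing,
            )
        except DegenerateError:
            lv_length_mm = None

    # LA volume at the atrial-maximum frame (biplane when both views exist)
    la_masks: dict[View, ChamberMaskSet] = {}
    for view in (View.A4C, View.A2C):
        if view not in by_view:
            continue
        try:
            clip, trace, _ed, _es = _best_clip(by_view[view], Chamber.LA)
        except (ManualSelectionRequiredError, EmptyTraceError):
            continue
        la_frame = clip.masks[int(np.nanargmax(np.where(np.isfinite(trace), trace, np.nan)))]
        if la_frame is not None and Chamber.LA in la_frame and la_frame[Chamber.LA].any():
            la_masks[view] = la_frame
    try:
        if len(la_masks) == 2:
            ms.la_volume = method_of_discs(
                {v.value: m for v, m in la_masks.items()}, Chamber.LA, n_discs, "biplane"
            )
        elif len(la_masks) == 1:
            (m,) = la_masks.values()
            ms.la_volume = method_of_discs(m, Chamber.LA, n_discs, "single")
    except DegenerateError:
        pass

    # RA volume: single-plane on the four-chamber view
    if View.A4C in by_view:
        try:
            clip, trace, _ed, _es = _best_clip(by_view[View.A4C], Chamber.RA)
            ra_frame = clip.masks[
                int(np.nanargmax(np.where(np.isfinite(trace), trace, np.nan)))
            ]
            if ra_frame is not None and Chamber.RA in ra_frame and ra_frame[Chamber.RA].any():
                ms.ra_volume = method_of_discs(ra_frame, Chamber.RA, n_discs, "single")
        except (ManualSelectionRequiredError, DegenerateError):
            pass

    # LV mass from the short-axis epi/endo areas at end-diastole
    if View.SAX in by_view and lv_length_mm is not None:
        try:
            clip, _trace, ed, _es = _best_clip(by_view[View.SAX], Chamber.LV)
            ed_masks = clip.masks[ed]
            if (
                ed_masks is not None
                and Chamber.LV_EPI in ed_masks
                and ed_masks[Chamber.LV_EPI].any()
            ):
                epi = ed_masks.area_cm2(Chamber.LV_EPI)
                endo = ed_masks.area_cm2(Chamber.LV)
                if epi > endo > 0:
                    ms.lv_mass = lv_mass_area_length(epi, endo, lv_length_mm / 10.0)
        except (ManualSelectionRequiredError, InvalidGeometryError):
            pass

    if bsa is not None:
        ms = classify_measurements(ms, bsa, sex, thresholds)
    return ms
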