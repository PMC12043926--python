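"""Core in-memory containers shared by every pipeline stage.

An :class:`UltrasoundFrame` is one grayscale image with physical pixel
spacing; a :class:`CineClip` is an ordered sequence of frames from one video;
a :class:`ChamberMaskSet` holds per-chamber binary masks on a frame grid with
a provenance tag (weak / model / qc_passed) so that training stages can
assert they only ever consume QC-passed labels.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import numpy as np

from .errors import ShapeError


class View(str, Enum):
    """Standard echocardiographic views."""

    A2C = "A2C"
    A4C = "A4C"
    SAX = "SAX"
    UNKNOWN = "unknown"


class Chamber(str, Enum):
    """Cardiac chambers (plus the LV epicardial contour for mass)."""

    LV = "LV"
    LA = "LA"
    RV = "RV"
    RA = "RA"
    LV_EPI = "LV_EPI"


class Provenance(str, Enum):
    """Where a mask set came from in the pipeline."""

    TRUTH = "truth"
    WEAK = "weak"
    MODEL = "model"
    QC_PASSED = "qc_passed"


#: Chambers each view is expected to segment.
VIEW_CHAMBERS: dict[View, tuple[Chamber, ...]] = {
    View.A2C: (Chamber.LV, Chamber.LA),
    View.A4C: (Chamber.LV, Chamber.LA, Chamber.RV, Chamber.RA),
    View.SAX: (Chamber.LV, Chamber.LV_EPI),
}


@dataclass
class UltrasoundFrame:
    """One grayscale frame with physical pixel spacing.

    Parameters
    ----------
    pixels
        2-D float array, intensities in [0, 1].
    pixel_spacing
        Isotropic spacing in mm/pixel (> 0).
    view
        View label, if known.
    frame_index
        Position of the frame within its clip.
    heart_rate
        Beats per minute, if recorded.
    field_of_view
        Depth of the imaging sector in mm, if recorded.
    """

    pixels: np.ndarray
    pixel_spacing: float
    view: View = View.UNKNOWN
    frame_index: int = 0
    heart_rate: Optional[float] = None
    field_of_view: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ShapeError("frame pixels must be a 2-D grid")
        if not (self.pixels.min() >= -1e-9 and self.pixels.max() <= 1 + 1e-9):
            raise ValueError("frame intensities must lie in [0, 1]")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def copy_with(self, **kw) -> "UltrasoundFrame":
        return replace(self, **kw)


@dataclass
class CineClip:
    """Ordered frames of one video."""

    frames: list[UltrasoundFrame]
    frame_rate: float
    study_id: str = "study0"
    video_id: str = "video0"

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.frames:
            shape = self.frames[0].shape
            spacing = self.frames[0].pixel_spacing
            for f in self.frames:
                if f.shape != shape:
                    raise ShapeError("all frames in a clip must share a grid size")
                if abs(f.pixel_spacing - spacing) > 1e-9:
                    raise ValueError("all frames in a clip must share pixel spacing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def view(self) -> View:
        return self.frames[0].view if self.frames else View.UNKNOWN

    @property
    def heart_rate(self) -> Optional[float]:
        return self.frames[0].heart_rate if self.frames else None


@dataclass
class ChamberMaskSet:
    """Per-chamber binary masks on one frame grid.

    Masks for distinct chambers must be pairwise disjoint; ``LV_EPI`` is the
    exception (it contains the LV cavity by construction).
    """

    masks: dict[Chamber, np.ndarray]
    pixel_spacing: float
    provenance: Provenance = Provenance.WEAK
    view: View = View.UNKNOWN

    def __post_init__(self) -> None:
        clean: dict[Chamber, np.ndarray] = {}
        shape = None
        for ch, m in self.masks.items():
            arr = np.asarray(m, dtype=bool)
            if arr.ndim != 2:
                raise ShapeError("masks must be 2-D")
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ShapeError("all masks in a set must share a grid")
            clean[Chamber(ch)] = arr
        self.masks = clean
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")

    def __contains__(self, chamber: Chamber) -> bool:
        return chamber in self.masks

    def __getitem__(self, chamber: Chamber) -> np.ndarray:
        return self.masks[chamber]

    @property
    def shape(self) -> Optional[tuple[int, int]]:
        for m in self.masks.values():
            return m.shape  # type: ignore[return-value]
        return None

    def area_cm2(self, chamber: Chamber) -> float:
        """Physical area of one chamber mask in cm^2."""
        mm2 = float(self.masks[chamber].sum()) * self.pixel_spacing**2
        return mm2 / 100.0

    def disjoint(self) -> bool:
        """True if cavity masks are pairwise disjoint (LV_EPI excluded)."""
        cavities = [m for ch, m in self.masks.items() if ch is not Chamber.LV_EPI]
        if len(cavities) < 2:
            return True
        total = np.zeros_like(cavities[0], dtype=np.int32)
        for m in cavities:
            total += m.astype(np.int32)
        return bool((total <= 1).all())

    def with_provenance(self, provenance: Provenance) -> "ChamberMaskSet":
        return ChamberMaskSet(
            masks={ch: m.copy() for ch, m in self.masks.items()},
            pixel_spacing=self.pixel_spacing,
            provenance=provenance,
            view=self.view,
        )


@dataclass
class MeasurementSet:
    """Guideline chamber measurements for one study.

    Volumes in mL, areas in cm^2, mass in grams, LVEF in percent.  Indexed
    variants (per BSA, m^2) and normal/abnormal calls are filled in by
    :func:`echoseg.measure.classify_measurements`.
    """

    lvedv: Optional[float] = None
    lvesv: Optional[float] = None
    lvef: Optional[float] = None
    lv_mass: Optional[float] = None
    la_volume: Optional[float] = None
    ra_volume: Optional[float] = None
    rveda: Optional[float] = None
    rvesa: Optional[float] = None
    indexed: dict[str, float] = field(default_factory=dict)
    category: dict[str, str] = field(default_factory=dict)
    grade: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict[str, Optional[float]]:
        return {
            "lvedv": self.lvedv,
            "lvesv": self.lvesv,
            "lvef": self.lvef,
            "lv_mass": self.lv_mass,
            "la_volume": self.la_volume,
            "ra_volume": self.ra_volume,
            "rveda": self.rveda,
            "rvesa": self.rvesa,
        }
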