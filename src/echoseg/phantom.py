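"""Seeded synthetic echo-phantom generator with analytic ground truth.

Generates sector-shaped grayscale frames containing dark blood-pool chambers
surrounded by bright myocardial wall bands, with multiplicative
Rayleigh-distributed speckle and optional angular signal dropout, plus cine
sequences whose chamber areas oscillate sinusoidally at a stated heart rate.
Every frame carries exact rasterized truth masks, and every study carries
the analytic measurements (EDV/ESV/EF/areas) of its generating geometry, so
each downstream stage of the pipeline can be scored against a closed-form
oracle.

Geometry is deliberately simple — ellipses in apical views (ventricle and
atrium separated by a bright valve-plane band) and an annulus in the
short-axis view — because simple geometry has analytic areas and volumes.
No attempt is made at physical wave simulation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import scipy.ndimage
import yaml

from .datatypes import (
    Chamber,
    ChamberMaskSet,
    CineClip,
    MeasurementSet,
    Provenance,
    UltrasoundFrame,
    View,
)
from .errors import InvalidGeometryError, NoElbowError, UndersampledError
from .train_loop import LossCurve

__all__ = [
    "EllipseGeometry",
    "PhantomSpec",
    "PhantomStudy",
    "make_phantom_frame",
    "make_cine",
    "make_loss_curve",
    "save_study",
    "load_study",
]

# display levels of the noise-free phantom (plus 0 outside the fan)
_LEVEL_TISSUE = 0.35
_LEVEL_WALL = 0.85
_LEVEL_CHAMBER = 0.05

_FAN_HALF_ANGLE = math.pi / 4  # 90-degree fan, apex at top-center
_APEX_DEPTH_MM = 2.0           # apex sits just below the top image edge


@dataclass
class EllipseGeometry:
    """One chamber as an ellipse in physical (depth, lateral) mm coordinates.

    ``orientation_deg`` = 0 puts the long axis along depth (vertical on the
    display).  For the SAX annulus the cavity is a circle (equal semi-axes)
    and the epicardial contour is the cavity dilated by the wall thickness.
    """

    center_depth: float
    center_lateral: float
    semi_long: float
    semi_short: float
    orientation_deg: float = 0.0

    @property
    def area_mm2(self) -> float:
        return math.pi * self.semi_long * self.semi_short

    def scaled(self, k: float) -> "EllipseGeometry":
        return replace(self, semi_long=self.semi_long * k, semi_short=self.semi_short * k)

    def spheroid_volume_ml(self) -> float:
        """Prolate spheroid volume (rotation about the long axis), mL."""
        return 4.0 / 3.0 * math.pi * self.semi_long * self.semi_short**2 / 1000.0


def _default_geometry(view: View) -> dict[Chamber, EllipseGeometry]:
    if view is View.A2C:
        return {
            Chamber.LV: EllipseGeometry(51.0, 0.0, 30.0, 18.0),
            Chamber.LA: EllipseGeometry(103.0, 0.0, 18.0, 15.0),
        }
    if view is View.A4C:
        return {
            Chamber.LV: EllipseGeometry(58.0, 18.0, 28.0, 15.0),
            Chamber.LA: EllipseGeometry(106.0, 16.0, 15.0, 13.0),
            Chamber.RV: EllipseGeometry(56.0, -18.0, 26.0, 12.0),
            Chamber.RA: EllipseGeometry(104.0, -15.0, 14.0, 12.0),
        }
    if view is View.SAX:
        return {Chamber.LV: EllipseGeometry(64.0, 0.0, 23.0, 23.0)}
    raise ValueError(f"no default geometry for view {view}")


@dataclass
class PhantomSpec:
    """Full description of one synthetic study.

    ``ef_target`` drives the ventricular sinusoid: ventricular semi-axes are
    scaled isotropically so that the prolate-spheroid volume excursion gives
    exactly the target ejection fraction; atria contract in counter-phase
    with area excursion ``atrial_area_fraction``.  ``lv_length_mm`` is the
    analytic LV long-axis diameter used for the truth LV-mass computation.
    """

    view: View = View.A2C
    image_size: int = 256
    pixel_spacing: float = 0.5
    chamber_geometry: Optional[dict[Chamber, EllipseGeometry]] = None
    wall_thickness: float = 8.0
    speckle_strength: float = 0.5
    dropout_fraction: float = 0.0
    heart_rate: float = 60.0
    frame_rate: float = 30.0
    n_frames: int = 32
    ef_target: float = 0.60
    atrial_area_fraction: float = 0.35
    lv_length_mm: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.view = View(self.view)
        if self.chamber_geometry is None:
            self.chamber_geometry = _default_geometry(self.view)
        if not (0.0 < self.ef_target < 1.0):
            raise ValueError("ef_target must lie in (0, 1)")
        if self.speckle_strength < 0:
            raise ValueError("speckle_strength must be >= 0")
        if not (0.0 <= self.dropout_fraction <= 1.0):
            raise ValueError("dropout_fraction must lie in [0, 1]")
        self._validate_geometry()

    # -- fan geometry ------------------------------------------------------
    def _grids(self) -> tuple[np.ndarray, np.ndarray]:
        """(depth mm from apex, lateral mm from midline) per pixel centre."""
        n = self.image_size
        idx = (np.arange(n) + 0.5) * self.pixel_spacing
        depth = idx[:, None] - _APEX_DEPTH_MM
        lateral = idx[None, :] - n * self.pixel_spacing / 2.0
        return np.broadcast_to(depth, (n, n)), np.broadcast_to(lateral, (n, n))

    def fan_mask(self) -> np.ndarray:
        depth, lateral = self._grids()
        max_depth = self.image_size * self.pixel_spacing - _APEX_DEPTH_MM - 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            angle = np.arctan2(np.abs(lateral), depth)
        radius = np.hypot(depth, lateral)
        return (depth > 0) & (angle <= _FAN_HALF_ANGLE) & (radius <= max_depth)

    def _inside_fan(self, geom: EllipseGeometry) -> bool:
        theta = np.linspace(0, 2 * math.pi, 256, endpoint=False)
        phi = math.radians(geom.orientation_deg)
        du = geom.semi_long * np.cos(theta)
        dv = geom.semi_short * np.sin(theta)
        d = geom.center_depth + du * math.cos(phi) - dv * math.sin(phi)
        x = geom.center_lateral + du * math.sin(phi) + dv * math.cos(phi)
        max_depth = self.image_size * self.pixel_spacing - _APEX_DEPTH_MM - 1.0
        ok = (d > 0) & (np.arctan2(np.abs(x), d) <= _FAN_HALF_ANGLE)
        ok &= np.hypot(d, x) <= max_depth
        return bool(ok.all())

    def _validate_geometry(self) -> None:
        geoms = dict(self.chamber_geometry)
        if self.view is View.SAX:
            lv = geoms[Chamber.LV]
            geoms[Chamber.LV_EPI] = replace(
                lv,
                semi_long=lv.semi_long + self.wall_thickness,
                semi_short=lv.semi_short + self.wall_thickness,
            )
        for ch, geom in geoms.items():
            if not self._inside_fan(geom):
                raise InvalidGeometryError(f"{ch.value} geometry extends outside the sector")
        # pairwise disjoint at full (end-diastolic) size
        rast = {
            ch: _rasterize_ellipse(self, g)
            for ch, g in geoms.items()
            if ch is not Chamber.LV_EPI
        }
        total = sum(m.astype(np.int32) for m in rast.values())
        if (total > 1).any():
            raise InvalidGeometryError("chamber regions overlap")

    # -- cardiac phase -----------------------------------------------------
    def ventricular_scale(self, phase: float) -> float:
        """Isotropic semi-axis scale of the ventricles at a cardiac phase.

        Area follows ``A(t) = A_ed - (A_ed - A_es)(1 - cos 2*pi*t)/2`` with
        ``A_es/A_ed = (1 - EF)^(2/3)`` so the spheroid volume excursion
        matches ``ef_target``.  Phase 0 is end-diastole.
        """
        area_ratio_es = (1.0 - self.ef_target) ** (2.0 / 3.0)
        a = 1.0 - (1.0 - area_ratio_es) * (1.0 - math.cos(2 * math.pi * phase)) / 2.0
        return math.sqrt(a)

    def atrial_scale(self, phase: float) -> float:
        """Atrial scale; atria are largest at ventricular end-systole."""
        area_ratio = 1.0 - self.atrial_area_fraction
        a = 1.0 - (1.0 - area_ratio) * (1.0 + math.cos(2 * math.pi * phase)) / 2.0
        return math.sqrt(a)

    def geometry_at_phase(self, phase: float) -> dict[Chamber, EllipseGeometry]:
        out: dict[Chamber, EllipseGeometry] = {}
        for ch, geom in self.chamber_geometry.items():
            k = (
                self.ventricular_scale(phase)
                if ch in (Chamber.LV, Chamber.RV)
                else self.atrial_scale(phase)
            )
            out[ch] = geom.scaled(k)
        if self.view is View.SAX:
            lv = out[Chamber.LV]
            out[Chamber.LV_EPI] = replace(
                lv,
                semi_long=lv.semi_long + self.wall_thickness,
                semi_short=lv.semi_short + self.wall_thickness,
            )
        return out

    # -- analytic truth ----------------------------------------------------
    def truth_measurements(self) -> MeasurementSet:
        """Closed-form measurements of the generating geometry."""
        ms = MeasurementSet()
        geoms = self.chamber_geometry
        if self.view in (View.A2C, View.A4C):
            lv = geoms[Chamber.LV]
            ms.lvedv = lv.spheroid_volume_ml()
            ms.lvesv = ms.lvedv * (1.0 - self.ef_target)
            ms.lvef = 100.0 * self.ef_target
            la = geoms[Chamber.LA]
            ms.la_volume = la.spheroid_volume_ml()
        if self.view is View.A4C:
            rv = geoms[Chamber.RV]
            ms.rveda = rv.area_mm2 / 100.0
            ms.rvesa = ms.rveda * (1.0 - self.ef_target) ** (2.0 / 3.0)
            ra = geoms[Chamber.RA]
            ms.ra_volume = ra.spheroid_volume_ml()
        if self.view is View.SAX:
            lv = geoms[Chamber.LV]
            endo = lv.area_mm2 / 100.0
            epi_geom = replace(
                lv,
                semi_long=lv.semi_long + self.wall_thickness,
                semi_short=lv.semi_short + self.wall_thickness,
            )
            epi = epi_geom.area_mm2 / 100.0
            from .measure import lv_mass_area_length

            ms.lv_mass = lv_mass_area_length(epi, endo, self.lv_length_mm / 10.0)
        return ms


def _rasterize_ellipse(spec: PhantomSpec, geom: EllipseGeometry) -> np.ndarray:
    depth, lateral = spec._grids()
    phi = math.radians(geom.orientation_deg)
    du = (depth - geom.center_depth) * math.cos(phi) + (lateral - geom.center_lateral) * math.sin(phi)
    dv = -(depth - geom.center_depth) * math.sin(phi) + (lateral - geom.center_lateral) * math.cos(phi)
    return (du / geom.semi_long) ** 2 + (dv / geom.semi_short) ** 2 <= 1.0


@dataclass
class PhantomStudy:
    """One synthetic study: cine clip(s), per-frame truth masks, analytic truth."""

    spec: PhantomSpec
    clips: list[CineClip]
    truth_masks: dict[str, list[ChamberMaskSet]]  # video_id -> per-frame masks
    truth_measurements: MeasurementSet

    @property
    def study_id(self) -> str:
        return self.clips[0].study_id if self.clips else "study0"


def make_phantom_frame(
    spec: PhantomSpec, phase: float
) -> tuple[UltrasoundFrame, ChamberMaskSet]:
    """Render one phantom frame and its exact truth masks at a cardiac phase.

    The noise-free frame is piecewise constant: dark chambers
    (:data:`_LEVEL_CHAMBER`) inside bright wall bands (:data:`_LEVEL_WALL`)
    over mid-gray tissue (:data:`_LEVEL_TISSUE`), zero outside the fan.
    Speckle multiplies the image by unit-mean Rayleigh noise; dropout zeroes
    an angular wedge covering ``dropout_fraction`` of the fan.
    """
    if not (0.0 <= phase < 1.0):
        raise ValueError("phase must lie in [0, 1)")
    geoms = spec.geometry_at_phase(phase)
    fan = spec.fan_mask()
    img = np.where(fan, _LEVEL_TISSUE, 0.0)

    chamber_masks: dict[Chamber, np.ndarray] = {}
    for ch, geom in geoms.items():
        chamber_masks[ch] = _rasterize_ellipse(spec, geom) & fan

    # bright wall band: each chamber dilated by the wall thickness
    wall = np.zeros_like(fan)
    for ch, geom in geoms.items():
        if ch is Chamber.LV_EPI:
            continue
        grown = replace(
            geom,
            semi_long=geom.semi_long + spec.wall_thickness,
            semi_short=geom.semi_short + spec.wall_thickness,
        )
        wall |= _rasterize_ellipse(spec, grown)
    img = np.where(wall & fan, _LEVEL_WALL, img)
    for ch, m in chamber_masks.items():
        if ch is Chamber.LV_EPI:
            continue
        img = np.where(m, _LEVEL_CHAMBER, img)

    rng = np.random.default_rng([spec.seed, int(round(phase * 10**6)), 9173])
    if spec.speckle_strength > 0:
        # unit-mean Rayleigh multiplier, blurred to mimic speckle correlation
        ray = rng.rayleigh(scale=1.0, size=img.shape) / math.sqrt(math.pi / 2.0)
        ray = scipy.ndimage.gaussian_filter(ray, sigma=1.0)
        mult = (1.0 - spec.speckle_strength) + spec.speckle_strength * ray
        img = img * mult
    if spec.dropout_fraction > 0:
        depth, lateral = spec._grids()
        angle = np.arctan2(lateral, np.maximum(depth, 1e-9))
        width = spec.dropout_fraction * 2 * _FAN_HALF_ANGLE
        center = rng.uniform(-_FAN_HALF_ANGLE + width / 2, _FAN_HALF_ANGLE - width / 2)
        wedge = np.abs(angle - center) <= width / 2
        img = np.where(wedge & fan, img * 0.05, img)
    img = np.clip(img, 0.0, 1.0)

    frame = UltrasoundFrame(
        pixels=img,
        pixel_spacing=spec.pixel_spacing,
        view=spec.view,
        heart_rate=spec.heart_rate,
    )
    masks = ChamberMaskSet(
        masks=chamber_masks,
        pixel_spacing=spec.pixel_spacing,
        provenance=Provenance.TRUTH,
        view=spec.view,
    )
    return frame, masks


def make_cine(spec: PhantomSpec, study_id: str = "study0", video_id: str = "video0") -> PhantomStudy:
    """Generate a cine phantom study covering at least one cardiac cycle.

    Per-frame truth areas follow ``A(t) = A_ed - (A_ed - A_es)(1 - cos
    2*pi*f*t)/2`` with ``f = heart_rate / 60``.

    Raises
    ------
    UndersampledError
        If the clip covers less than one full cycle or samples fewer than 4
        frames per cycle.
    """
    f = spec.heart_rate / 60.0
    if spec.n_frames < 2 or (spec.n_frames - 1) / spec.frame_rate < 1.0 / f - 1e-9:
        raise UndersampledError("cine must cover at least one full cardiac cycle")
    if spec.frame_rate < 4.0 * f:
        raise UndersampledError("fewer than 4 frames per cardiac cycle")
    frames: list[UltrasoundFrame] = []
    masks: list[ChamberMaskSet] = []
    for i in range(spec.n_frames):
        phase = (f * i / spec.frame_rate) % 1.0
        frame, mask = make_phantom_frame(spec, phase)
        frame.frame_index = i
        frames.append(frame)
        masks.append(mask)
    clip = CineClip(frames=frames, frame_rate=spec.frame_rate, study_id=study_id, video_id=video_id)
    return PhantomStudy(
        spec=spec,
        clips=[clip],
        truth_masks={video_id: masks},
        truth_measurements=spec.truth_measurements(),
    )


def make_loss_curve(
    elbow_epoch: int,
    pre_rate: float,
    post_rate: float,
    noise_sd: float,
    n_epochs: int,
    seed: int = 0,
    start_loss: float = 0.9,
) -> LossCurve:
    """Synthetic validation-loss curve with a known elbow.

    Expectation decays linearly at ``pre_rate`` per epoch until
    ``elbow_epoch`` and at ``post_rate`` afterwards, so the discrete
    curvature maximum of the expectation sits exactly at the elbow; Gaussian
    noise of ``noise_sd`` is added on top.

    Raises
    ------
    NoElbowError
        If ``pre_rate == post_rate`` (a straight line has no elbow).
    """
    if not (1 <= elbow_epoch < n_epochs):
        raise ValueError("need 1 <= elbow_epoch < n_epochs")
    if post_rate < 0 or pre_rate <= post_rate:
        if math.isclose(pre_rate, post_rate):
            raise NoElbowError("pre_rate == post_rate: straight line, no elbow")
        raise ValueError("need pre_rate > post_rate >= 0")
    epochs = np.arange(n_epochs)
    expectation = (
        start_loss
        - pre_rate * np.minimum(epochs, elbow_epoch)
        - post_rate * np.maximum(0, epochs - elbow_epoch)
    )
    if expectation[-1] < 0:
        raise ValueError("rates drive the expected loss below zero")
    rng = np.random.default_rng([seed, 40087])
    losses = expectation + rng.normal(0.0, noise_sd, size=n_epochs)
    return LossCurve(epoch_index=epochs, validation_loss=losses)


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def save_study(study: PhantomStudy, out_dir, image_format: str = "png") -> Path:
    """Write a study as PNG frames + NPZ masks + a YAML manifest."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = study.spec
    manifest = {
        "view": spec.view.value,
        "pixel_spacing": spec.pixel_spacing,
        "heart_rate": spec.heart_rate,
        "frame_rate": spec.frame_rate,
        "n_frames": spec.n_frames,
        "ef_target": spec.ef_target,
        "seed": spec.seed,
        "truth": {k: v for k, v in study.truth_measurements.as_dict().items() if v is not None},
        "videos": [],
    }
    for clip in study.clips:
        vdir = out / clip.video_id
        vdir.mkdir(exist_ok=True)
        for i, frame in enumerate(clip.frames):
            iio.imwrite(
                vdir / f"frame{i:04d}.{image_format}",
                (frame.pixels * 255).astype(np.uint8),
            )
        masks = study.truth_masks[clip.video_id]
        chambers = sorted({ch.value for ms in masks for ch in ms.masks})
        stacks = {
            ch: np.stack([ms.masks.get(Chamber(ch), np.zeros(ms.shape, bool)) for ms in masks])
            for ch in chambers
        }
        np.savez(vdir / "truth_masks.npz", **stacks)
        manifest["videos"].append({"video_id": clip.video_id, "n_frames": len(clip)})
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    return out


def load_study(study_dir) -> tuple[list[CineClip], dict[str, list[ChamberMaskSet]], dict]:
    """Read back a study written by :func:`save_study`."""
    import imageio.v3 as iio

    root = Path(study_dir)
    with open(root / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    spacing = float(manifest["pixel_spacing"])
    view = View(manifest["view"])
    clips, truth = [], {}
    for video in manifest["videos"]:
        vdir = root / video["video_id"]
        frames = []
        for i in range(video["n_frames"]):
            px = iio.imread(vdir / f"frame{i:04d}.png").astype(np.float64) / 255.0
            frames.append(
                UltrasoundFrame(
                    pixels=px,
                    pixel_spacing=spacing,
                    view=view,
                    frame_index=i,
                    heart_rate=manifest.get("heart_rate"),
                )
            )
        clips.append(
            CineClip(
                frames=frames,
                frame_rate=float(manifest["frame_rate"]),
                study_id=root.name,
                video_id=video["video_id"],
            )
        )
        npz = np.load(vdir / "truth_masks.npz")
        masks = []
        for i in range(video["n_frames"]):
            masks.append(
                ChamberMaskSet(
                    masks={Chamber(ch): npz[ch][i] for ch in npz.files},
                    pixel_spacing=spacing,
                    provenance=Provenance.TRUTH,
                    view=view,
                )
            )
        truth[video["video_id"]] = masks
    return clips, truth, manifest
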