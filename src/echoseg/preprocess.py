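"""Sector extraction and geometric/intensity standardization.

Frames are resampled to 0.5 mm/pixel and resized to 256 x 256 for
segmentation or 480 x 480 for edge detection, with intensities min-max
normalized to [0, 1].  The ultrasound fan is located in raw captures (which
may carry burned-in UI elements) as the largest connected component of
above-background pixels, closed by its convex hull.
"""
from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import skimage.measure
import skimage.morphology
import skimage.transform

from .datatypes import ChamberMaskSet, CineClip, UltrasoundFrame, View
from .errors import MissingSpacingError, NoROIError

__all__ = [
    "TARGET_SPACING",
    "TARGET_SIZE",
    "extract_sector_roi",
    "standardize_frame",
    "standardize_masks",
    "standardize_clip",
    "read_dicom",
    "write_dicom_frame",
    "read_image_stack",
]

#: standard grid: 0.5 mm/pixel; 256 px for segmentation, 480 px for edges
TARGET_SPACING = 0.5
TARGET_SIZE = {"segmentation": 256, "edge": 480}

#: assumed sector depth when no spacing metadata exists (200 mm field of view)
DEFAULT_FOV_MM = 200.0


def extract_sector_roi(
    raw_image: np.ndarray, metadata: Optional[dict] = None
) -> UltrasoundFrame:
    """Locate the fan-shaped imaging region and zero everything else.

    The fan is the convex hull of the largest connected component of
    above-background pixels.  Pixel spacing is taken from
    ``metadata['pixel_spacing']`` when present, otherwise estimated from the
    fan's depth extent and ``metadata['field_of_view']`` (falling back to a
    200 mm field of view).

    Raises
    ------
    NoROIError
        If the largest bright component covers < 5% of the image.
    """
    metadata = metadata or {}
    img = np.asarray(raw_image, dtype=np.float64)
    if img.max() > 1.0:
        img = img / img.max()
    bright = img > 0.02
    labels = skimage.measure.label(bright)
    if labels.max() == 0:
        raise NoROIError("no above-background pixels")
    sizes = np.bincount(labels.ravel())[1:]
    main = int(np.argmax(sizes)) + 1
    if sizes[main - 1] < 0.05 * img.size:
        raise NoROIError("largest bright region covers < 5% of the image")
    fan = skimage.morphology.convex_hull_image(labels == main)
    rows, cols = np.nonzero(fan)
    cropped = np.where(fan, img, 0.0)[rows.min(): rows.max() + 1, cols.min(): cols.max() + 1]

    spacing = metadata.get("pixel_spacing")
    if spacing is None:
        fov = metadata.get("field_of_view", DEFAULT_FOV_MM)
        spacing = fov / (rows.max() - rows.min() + 1)
    return UltrasoundFrame(
        pixels=np.clip(cropped, 0.0, 1.0),
        pixel_spacing=float(spacing),
        view=View(metadata.get("view", View.UNKNOWN)),
        heart_rate=metadata.get("heart_rate"),
        field_of_view=metadata.get("field_of_view"),
    )


def _resample(img: np.ndarray, factor: float, order: int) -> np.ndarray:
    out_shape = (max(1, round(img.shape[0] * factor)), max(1, round(img.shape[1] * factor)))
    if out_shape == img.shape:
        return img.copy()
    return skimage.transform.resize(
        img.astype(np.float64),
        out_shape,
        order=order,
        anti_aliasing=(order > 0 and factor < 1),
        preserve_range=True,
    )


def _pad_crop_center(img: np.ndarray, size: int) -> np.ndarray:
    """Symmetric zero-pad then center-crop to a square ``size`` grid."""
    out = img
    for axis in (0, 1):
        n = out.shape[axis]
        if n < size:
            before = (size - n) // 2
            after = size - n - before
            pads = [(0, 0), (0, 0)]
            pads[axis] = (before, after)
            out = np.pad(out, pads)
        elif n > size:
            start = (n - size) // 2
            out = out.take(range(start, start + size), axis=axis)
    return out


def standardize_frame(frame: UltrasoundFrame, target: str = "segmentation") -> UltrasoundFrame:
    """Resample to 0.5 mm/px, pad/crop to the target grid, min-max rescale.

    Bilinear interpolation for images; intensities are min-max rescaled to
    [0, 1] (a constant frame maps to all zeros).  Idempotent: a frame
    already on the target grid passes through unchanged geometry.
    """
    if target not in TARGET_SIZE:
        raise ValueError(f"target must be one of {sorted(TARGET_SIZE)}")
    if frame.pixel_spacing is None or frame.pixel_spacing <= 0:
        raise MissingSpacingError("frame has no usable pixel spacing")
    factor = frame.pixel_spacing / TARGET_SPACING
    img = _resample(frame.pixels, factor, order=1)
    # rescale before padding so a constant frame maps to zeros rather than
    # being stretched against its own zero padding
    lo, hi = img.min(), img.max()
    img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    img = _pad_crop_center(img, TARGET_SIZE[target])
    return UltrasoundFrame(
        pixels=img,
        pixel_spacing=TARGET_SPACING,
        view=frame.view,
        frame_index=frame.frame_index,
        heart_rate=frame.heart_rate,
        field_of_view=frame.field_of_view,
    )


def standardize_masks(masks: ChamberMaskSet, target: str = "segmentation") -> ChamberMaskSet:
    """Companion mask resampling: nearest-neighbour, same pad/crop as frames."""
    if target not in TARGET_SIZE:
        raise ValueError(f"target must be one of {sorted(TARGET_SIZE)}")
    factor = masks.pixel_spacing / TARGET_SPACING
    out = {}
    for ch, m in masks.masks.items():
        r = _resample(m.astype(np.float64), factor, order=0)
        out[ch] = _pad_crop_center(r, TARGET_SIZE[target]) > 0.5
    return ChamberMaskSet(
        masks=out,
        pixel_spacing=TARGET_SPACING,
        provenance=masks.provenance,
        view=masks.view,
    )


def standardize_clip(clip: CineClip, target: str = "segmentation") -> CineClip:
    return CineClip(
        frames=[standardize_frame(f, target) for f in clip.frames],
        frame_rate=clip.frame_rate,
        study_id=clip.study_id,
        video_id=clip.video_id,
    )


# --------------------------------------------------------------------------
# file readers / writers
# --------------------------------------------------------------------------

def _dicom_spacing(ds) -> Optional[float]:
    if getattr(ds, "PixelSpacing", None):
        return float(ds.PixelSpacing[0])
    regions = getattr(ds, "SequenceOfUltrasoundRegions", None)
    if regions:
        delta = getattr(regions[0], "PhysicalDeltaX", None)
        if delta:  # PhysicalDeltaX is in cm/px for ultrasound regions
            return abs(float(delta)) * 10.0
    return None


def read_dicom(path, view: View = View.UNKNOWN) -> CineClip:
    """Read a single- or multi-frame DICOM into a CineClip."""
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    elif arr.ndim == 4:  # RGB: luminance
        arr = arr.mean(axis=-1)
    if arr.max() > 0:
        arr = arr / arr.max()
    spacing = _dicom_spacing(ds)
    if spacing is None:
        raise MissingSpacingError(f"no pixel spacing in {path}")
    rate = float(getattr(ds, "CineRate", 0) or 0)
    if rate <= 0:
        frame_time = float(getattr(ds, "FrameTime", 0) or 0)
        rate = 1000.0 / frame_time if frame_time > 0 else 30.0
    hr = getattr(ds, "HeartRate", None)
    frames = [
        UltrasoundFrame(
            pixels=np.clip(a, 0, 1),
            pixel_spacing=spacing,
            view=view,
            frame_index=i,
            heart_rate=float(hr) if hr else None,
        )
        for i, a in enumerate(arr)
    ]
    return CineClip(frames=frames, frame_rate=rate, study_id=Path(path).stem)


def write_dicom_frame(frame: UltrasoundFrame, path) -> None:
    """Write one frame as a minimal secondary-capture DICOM file."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "US"
    ds.Rows, ds.Columns = frame.pixels.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.PixelSpacing = [frame.pixel_spacing, frame.pixel_spacing]
    if frame.heart_rate:
        ds.HeartRate = str(int(round(frame.heart_rate)))
    ds.PixelData = (frame.pixels * 255).astype(np.uint8).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def read_image_stack(
    directory, pixel_spacing: float, frame_rate: float = 30.0, view: View = View.UNKNOWN
) -> CineClip:
    """Read a directory of PNG/TIFF frames (sorted by name) into a clip."""
    import imageio.v3 as iio

    paths = sorted(
        p for p in Path(directory).iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    if not paths:
        raise FileNotFoundError(f"no image frames under {directory}")
    frames = []
    for i, p in enumerate(paths):
        arr = iio.imread(p).astype(np.float64)
        if arr.ndim == 3:
            arr = arr.mean(axis=-1)
        if arr.max() > 0:
            arr = arr / arr.max()
        frames.append(
            UltrasoundFrame(pixels=arr, pixel_spacing=pixel_spacing, view=view, frame_index=i)
        )
    return CineClip(frames=frames, frame_rate=frame_rate, study_id=Path(directory).name)
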