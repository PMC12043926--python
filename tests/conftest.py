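"""Shared fixtures: rasterized geometry and small phantom studies."""
import numpy as np
import pytest

from echoseg.datatypes import Chamber, ChamberMaskSet, View
from echoseg.phantom import PhantomSpec, make_cine, make_phantom_frame


def rasterize_disc(radius_mm: float, spacing: float, pad_px: int = 8) -> np.ndarray:
    """Boolean disc of the given physical radius, centred in a square grid."""
    r_px = radius_mm / spacing
    n = int(2 * r_px) + 2 * pad_px
    rr, cc = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2.0
    return (rr - c) ** 2 + (cc - c) ** 2 <= r_px**2


def rasterize_ellipse(a_mm: float, b_mm: float, spacing: float, pad_px: int = 8) -> np.ndarray:
    """Ellipse with semi-axes (a, b) mm; a along rows."""
    a_px, b_px = a_mm / spacing, b_mm / spacing
    n = int(2 * max(a_px, b_px)) + 2 * pad_px
    rr, cc = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2.0
    return ((rr - c) / a_px) ** 2 + ((cc - c) / b_px) ** 2 <= 1.0


@pytest.fixture(scope="session")
def clean_a2c_frame():
    """Noise-free A2C phantom frame at mid-cycle phase with its truth masks."""
    spec = PhantomSpec(view=View.A2C, speckle_strength=0.0)
    return make_phantom_frame(spec, 0.25)


@pytest.fixture(scope="session")
def clean_sax_frame():
    spec = PhantomSpec(view=View.SAX, speckle_strength=0.0)
    return make_phantom_frame(spec, 0.0)


@pytest.fixture(scope="session")
def tiny_a2c_study():
    """Speckled tiny-grid A2C cine study (64 px, 2 mm/px)."""
    spec = PhantomSpec(
        view=View.A2C,
        image_size=64,
        pixel_spacing=2.0,
        speckle_strength=0.5,
        n_frames=16,
        frame_rate=15.0,
        seed=11,
    )
    return make_cine(spec)


def disc_mask_set(radius_mm: float, spacing: float, chamber=Chamber.LV) -> ChamberMaskSet:
    return ChamberMaskSet(
        masks={chamber: rasterize_disc(radius_mm, spacing)}, pixel_spacing=spacing
    )
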