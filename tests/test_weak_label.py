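"""Weak-label creation: blood-pool recipe, Hough circles, fills, relabelling."""
import numpy as np
import pytest
import skimage.morphology

from conftest import rasterize_disc, rasterize_ellipse
from echoseg.datatypes import Chamber, ChamberMaskSet, Provenance, UltrasoundFrame, View
from echoseg.errors import (
    BadRangeError,
    DegenerateMaskError,
    InvalidInputError,
    UnassignableError,
)
from echoseg.phantom import PhantomSpec, make_phantom_frame
from echoseg.stats import dice_score
from echoseg import weak_label


class TestA2CWeakLabel:
    def test_noise_free_phantom_dice(self, clean_a2c_frame):
        frame, truth = clean_a2c_frame
        out = weak_label.a2c_weak_label(frame)
        assert out is not None
        assert dice_score(out[Chamber.LV], truth[Chamber.LV]) >= 0.7
        assert dice_score(out[Chamber.LA], truth[Chamber.LA]) >= 0.7
        assert out.provenance is Provenance.WEAK
        assert out.disjoint()

    def test_all_bright_frame_rejected(self):
        frame = UltrasoundFrame(pixels=np.ones((128, 128)) * 0.9, pixel_spacing=0.5)
        assert weak_label.a2c_weak_label(frame) is None

    def test_single_dark_component_rejected(self):
        img = np.full((256, 256), 0.6)
        img[100:160, 100:160] = 0.05  # one pool only
        frame = UltrasoundFrame(pixels=img, pixel_spacing=0.5)
        assert weak_label.a2c_weak_label(frame) is None

    def test_flip_equivariance(self, clean_a2c_frame):
        """Horizontal flip commutes with the recipe (chambers are relabeled in place)."""
        frame, _ = clean_a2c_frame
        flipped = frame.copy_with(pixels=frame.pixels[:, ::-1].copy())
        out = weak_label.a2c_weak_label(frame)
        out_f = weak_label.a2c_weak_label(flipped)
        assert out is not None and out_f is not None
        for ch in (Chamber.LV, Chamber.LA):
            assert dice_score(out_f[ch][:, ::-1], out[ch]) > 0.98


class TestHoughCircles:
    def test_phantom_annulus_recovered(self, clean_sax_frame):
        frame, truth = clean_sax_frame
        hyps = weak_label.hough_circle_detect(frame, (15.0, 45.0), max_candidates=3)
        assert hyps
        top = hyps[0]
        rows, cols = np.nonzero(truth[Chamber.LV])
        center = (rows.mean(), cols.mean())
        radius_px = 23.0 / frame.pixel_spacing
        assert abs(top.center[0] - center[0]) <= 2
        assert abs(top.center[1] - center[1]) <= 2
        assert abs(top.radius - radius_px) <= 2

    def test_blank_frame_gives_empty_list(self):
        frame = UltrasoundFrame(pixels=np.zeros((128, 128)), pixel_spacing=0.5)
        assert weak_label.hough_circle_detect(frame) == []

    def test_two_concentric_rings_both_found(self):
        img = np.zeros((200, 200))
        for r in (40, 70):
            ring = rasterize_disc(r * 0.5, 0.5, pad_px=100 - r)
            band = ring & ~skimage.morphology.erosion(ring, skimage.morphology.disk(2))
            img[band] = 1.0
        frame = UltrasoundFrame(pixels=img, pixel_spacing=0.5)
        hyps = weak_label.hough_circle_detect(
            frame, (15.0, 45.0), max_candidates=2, min_center_distance_mm=1.0
        )
        radii = sorted(h.radius for h in hyps[:2])
        assert radii[0] == pytest.approx(40, abs=3)
        assert radii[1] == pytest.approx(70, abs=3)

    def test_inverted_radius_range(self, clean_sax_frame):
        frame, _ = clean_sax_frame
        with pytest.raises(BadRangeError):
            weak_label.hough_circle_detect(frame, (45.0, 15.0))


class TestEdgeFill:
    def test_circle_outline_fills_to_disc(self):
        disc = rasterize_disc(15.0, 1.0)
        outline = disc & ~skimage.morphology.erosion(disc, skimage.morphology.disk(1))
        filled = weak_label.edge_to_filled_mask(outline.astype(float), 0.5, 1.0)
        assert dice_score(filled, disc) > 0.98

    def test_zero_edge_map_gives_empty_mask(self):
        out = weak_label.edge_to_filled_mask(np.zeros((64, 64)), 0.5, 1.0)
        assert not out.any()

    def test_c_shaped_contour_gap_behavior(self):
        """Small gaps close and fill; wide gaps leave nothing enclosed."""
        disc = rasterize_disc(15.0, 1.0)
        outline = disc & ~skimage.morphology.erosion(disc, skimage.morphology.disk(1))
        n = outline.shape[0]
        cols = np.arange(n) - (n - 1) / 2
        rows = np.arange(n)[:, None] - (n - 1) / 2
        small_gap = outline & ~((np.abs(rows) < 1) & (cols > 10))
        wide_gap = outline & ~((np.abs(rows) < 12) & (cols > 5))
        filled_small = weak_label.edge_to_filled_mask(
            small_gap.astype(float), 0.5, 1.0, closing_radius_mm=3.0
        )
        filled_wide = weak_label.edge_to_filled_mask(
            wide_gap.astype(float), 0.5, 1.0, closing_radius_mm=3.0
        )
        assert dice_score(filled_small, disc) > 0.9
        assert not filled_wide.any()

    def test_concentric_rings_resolve_to_cavity(self):
        outer = rasterize_disc(20.0, 1.0, pad_px=6)
        inner = rasterize_disc(12.0, 1.0, pad_px=14)
        ring = lambda d: d & ~skimage.morphology.erosion(d, skimage.morphology.disk(1))
        both = ring(outer) | ring(inner)
        filled = weak_label.edge_to_filled_mask(both.astype(float), 0.5, 1.0, 1.0)
        assert dice_score(filled, inner) > 0.95


class TestEpiEndo:
    def test_disc_radii(self):
        cavity = rasterize_disc(20.0, 0.5, pad_px=24)
        epi, endo = weak_label.make_epi_endo_labels(cavity, 0.5, 9.0, 1.0)
        r_epi = np.sqrt(epi.sum() * 0.25 / np.pi)
        r_endo = np.sqrt(endo.sum() * 0.25 / np.pi)
        assert r_epi * 0.5 == pytest.approx(29.0 * 0.5, abs=0.5)  # mm
        assert r_endo * 0.5 == pytest.approx(19.0 * 0.5, abs=0.5)
        assert (endo & ~cavity).sum() == 0
        assert (cavity & ~epi).sum() == 0

    def test_zero_margins_are_identity(self):
        cavity = rasterize_disc(10.0, 0.5)
        epi, endo = weak_label.make_epi_endo_labels(cavity, 0.5, 0.0, 0.0)
        assert np.array_equal(epi, cavity) and np.array_equal(endo, cavity)

    def test_over_erosion_is_degenerate(self):
        cavity = rasterize_disc(1.0, 0.5)
        with pytest.raises(DegenerateMaskError):
            weak_label.make_epi_endo_labels(cavity, 0.5, 9.0, 2.0)


def _two_plus_two(flip=False):
    """Synthetic A4C-style 2-ventricle + 2-atrium component prediction."""
    grid = np.zeros((128, 128), bool)
    def blob(r, c):
        m = grid.copy()
        m[r - 10: r + 10, c - 8: c + 8] = True
        return m
    lv = blob(45, 85) | blob(45, 40)       # two ventricle comps
    la = blob(95, 85) | blob(95, 40)       # two atrium comps
    if flip:
        lv, la = lv[:, ::-1], la[:, ::-1]
    return ChamberMaskSet(
        masks={Chamber.LV: lv, Chamber.LA: la},
        pixel_spacing=1.0,
        provenance=Provenance.MODEL,
        view=View.A4C,
    )


class TestReassignA4C:
    def test_standard_layout(self):
        out = weak_label.reassign_a4c_labels(_two_plus_two(), "LV_on_image_right")
        assert set(out.masks) == {Chamber.LV, Chamber.LA, Chamber.RV, Chamber.RA}
        rows, cols = np.nonzero(out[Chamber.LV])
        assert cols.mean() > 64 and rows.mean() < 64
        rows, cols = np.nonzero(out[Chamber.RA])
        assert cols.mean() < 64 and rows.mean() > 64

    def test_mirrored_frame_with_flipped_flag(self):
        ref = weak_label.reassign_a4c_labels(_two_plus_two(), "LV_on_image_right")
        mirrored = weak_label.reassign_a4c_labels(
            _two_plus_two(flip=True), "LV_on_image_left"
        )
        for ch in ref.masks:
            assert np.array_equal(mirrored[ch][:, ::-1], ref[ch])

    def test_three_components_unassignable(self):
        pred = _two_plus_two()
        lv = pred[Chamber.LV].copy()
        lv[5:9, 5:9] = True  # third ventricle blob
        bad = ChamberMaskSet(
            masks={Chamber.LV: lv, Chamber.LA: pred[Chamber.LA]},
            pixel_spacing=1.0, view=View.A4C,
        )
        with pytest.raises(UnassignableError):
            weak_label.reassign_a4c_labels(bad)

    def test_ordering_violation_unassignable(self):
        pred = _two_plus_two()
        flipped_up_down = ChamberMaskSet(
            masks={Chamber.LV: pred[Chamber.LA], Chamber.LA: pred[Chamber.LV]},
            pixel_spacing=1.0, view=View.A4C,
        )
        with pytest.raises(UnassignableError):
            weak_label.reassign_a4c_labels(flipped_up_down)


class TestStretchRVApex:
    def _masks(self, rv_len=60.0, lv_len=100.0):
        lv = rasterize_ellipse(lv_len / 2, 20.0, 1.0, pad_px=30)
        n = lv.shape[0]
        rv_small = rasterize_ellipse(rv_len / 2, 12.0, 1.0, pad_px=4)
        rv = np.zeros((n, n), bool)
        r0 = n // 2 - rv_small.shape[0] // 2 + int((lv_len - rv_len) / 2)
        rv[r0: r0 + rv_small.shape[0], 8: 8 + rv_small.shape[1]] = rv_small
        # shift LV right so masks are disjoint
        lv_sh = np.zeros_like(lv)
        lv_sh[:, 60:] = lv[:, :-60]
        return rv, lv_sh

    def test_stretch_reaches_target_length(self):
        rv, lv = self._masks()
        res = weak_label.stretch_rv_apex(rv, lv, 1.0, target_length_ratio=0.9)
        from echoseg.measure import mask_long_axis

        lv_len, _, _ = mask_long_axis(lv, 1.0)
        rv_len, _, _ = mask_long_axis(res.mask, 1.0)
        assert res.reached_target
        assert rv_len == pytest.approx(0.9 * lv_len, abs=2.0)
        assert not (res.mask & lv).any()
        import skimage.measure as skm

        assert skm.label(res.mask).max() == 1  # stays one component

    def test_noop_when_already_long_enough(self):
        rv, lv = self._masks(rv_len=95.0)
        res = weak_label.stretch_rv_apex(rv, lv, 1.0, target_length_ratio=0.9)
        assert res.reached_target
        assert np.array_equal(res.mask, rv)

    def test_overlapping_inputs_invalid(self):
        rv, lv = self._masks()
        with pytest.raises(InvalidInputError):
            weak_label.stretch_rv_apex(rv, rv, 1.0)
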