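"""Phantom generator: analytic-area conservation, sinusoid truth, determinism."""
import math

import numpy as np
import pytest

from echoseg.datatypes import Chamber, View
from echoseg.errors import InvalidGeometryError, NoElbowError, UndersampledError
from echoseg.measure import area_trace, method_of_discs, select_cycle_frames, fit_cardiac_sinusoid
from echoseg.phantom import (
    EllipseGeometry,
    PhantomSpec,
    load_study,
    make_cine,
    make_loss_curve,
    make_phantom_frame,
    save_study,
)


class TestFrameGeneration:
    def test_sax_circle_area_within_one_percent(self):
        """Rasterized truth area of a 23 mm circle matches pi*r^2 to <=1%."""
        spec = PhantomSpec(view=View.SAX, speckle_strength=0.0)
        _, masks = make_phantom_frame(spec, 0.0)
        analytic = math.pi * 23.0**2 / 100.0
        assert masks.area_cm2(Chamber.LV) == pytest.approx(analytic, rel=0.01)

    def test_noise_free_frame_is_piecewise_constant(self, clean_a2c_frame):
        frame, _ = clean_a2c_frame
        levels = np.unique(frame.pixels)
        assert len(levels) <= 4  # background, tissue, wall, chamber

    def test_bright_wall_band_surrounds_dark_chamber(self, clean_a2c_frame):
        frame, masks = clean_a2c_frame
        import skimage.morphology

        lv = masks[Chamber.LV]
        band = skimage.morphology.dilation(lv, skimage.morphology.disk(3)) & ~lv
        assert frame.pixels[lv].max() < 0.1
        assert frame.pixels[band].mean() > 0.7

    def test_same_spec_same_seed_bit_identical(self):
        spec = PhantomSpec(view=View.A2C, seed=5)
        f1, m1 = make_phantom_frame(spec, 0.3)
        f2, m2 = make_phantom_frame(spec, 0.3)
        assert np.array_equal(f1.pixels, f2.pixels)
        assert all(np.array_equal(m1[ch], m2[ch]) for ch in m1.masks)

    def test_chambers_disjoint_and_inside_sector(self):
        for view in (View.A2C, View.A4C, View.SAX):
            spec = PhantomSpec(view=view, speckle_strength=0.0)
            _, masks = make_phantom_frame(spec, 0.0)
            assert masks.disjoint()
            fan = spec.fan_mask()
            for ch, m in masks.masks.items():
                assert not (m & ~fan).any(), f"{ch} leaks outside the fan"

    def test_geometry_outside_sector_rejected(self):
        with pytest.raises(InvalidGeometryError):
            PhantomSpec(
                view=View.SAX,
                chamber_geometry={Chamber.LV: EllipseGeometry(20.0, 40.0, 30.0, 30.0)},
            )

    def test_dropout_darkens_a_wedge(self):
        spec0 = PhantomSpec(view=View.A2C, speckle_strength=0.0, dropout_fraction=0.0)
        spec1 = PhantomSpec(view=View.A2C, speckle_strength=0.0, dropout_fraction=0.3)
        f0, _ = make_phantom_frame(spec0, 0.0)
        f1, _ = make_phantom_frame(spec1, 0.0)
        assert (f1.pixels < f0.pixels - 0.05).mean() > 0.02


class TestCine:
    def test_truth_ef_recovered_by_disc_oracle(self):
        """EF recomputed from rasterized truth masks matches the target."""
        spec = PhantomSpec(view=View.A2C, ef_target=0.6, speckle_strength=0.0)
        study = make_cine(spec)
        masks = study.truth_masks["video0"]
        trace = area_trace(masks, Chamber.LV)
        fit = fit_cardiac_sinusoid(trace, spec.heart_rate, spec.frame_rate)
        _, ed, es = select_cycle_frames({"video0": (fit, trace)})
        edv = method_of_discs(masks[ed], Chamber.LV, 20, "single")
        esv = method_of_discs(masks[es], Chamber.LV, 20, "single")
        assert (edv - esv) / edv == pytest.approx(0.6, abs=0.01)

    def test_area_follows_stated_sinusoid(self):
        spec = PhantomSpec(view=View.A2C, ef_target=0.5, speckle_strength=0.0)
        study = make_cine(spec)
        trace = area_trace(study.truth_masks["video0"], Chamber.LV)
        f = spec.heart_rate / 60.0
        t = np.arange(spec.n_frames) / spec.frame_rate
        a_ed = trace[0]
        a_es = a_ed * (1 - 0.5) ** (2.0 / 3.0)
        expected = a_ed - (a_ed - a_es) * (1 - np.cos(2 * np.pi * f * t)) / 2
        rms = np.sqrt(np.mean((trace - expected) ** 2)) / a_ed
        assert rms < 0.01

    def test_two_cycles_give_exactly_two_area_maxima(self):
        spec = PhantomSpec(
            view=View.A2C, heart_rate=60.0, frame_rate=30.0, n_frames=60,
            speckle_strength=0.0,
        )
        study = make_cine(spec)
        trace = area_trace(study.truth_masks["video0"], Chamber.LV)
        maxima = np.flatnonzero(trace >= trace.max() - 1e-9)
        assert list(maxima) == [0, 30]

    def test_single_frame_is_undersampled(self):
        with pytest.raises(UndersampledError):
            make_cine(PhantomSpec(view=View.A2C, n_frames=1))

    def test_low_frame_rate_is_undersampled(self):
        with pytest.raises(UndersampledError):
            make_cine(PhantomSpec(view=View.A2C, heart_rate=120.0, frame_rate=6.0, n_frames=30))

    def test_truth_ef_equals_target(self):
        for ef in (0.3, 0.62):
            spec = PhantomSpec(view=View.A2C, ef_target=ef)
            assert spec.truth_measurements().lvef == pytest.approx(100 * ef, abs=1e-6)

    def test_increasing_ef_decreases_truth_esv(self):
        esvs = [
            PhantomSpec(view=View.A2C, ef_target=ef).truth_measurements().lvesv
            for ef in (0.3, 0.5, 0.7)
        ]
        assert esvs[0] > esvs[1] > esvs[2]


class TestLossCurveGenerator:
    def test_curvature_maximum_at_elbow_brute_force(self):
        """Second difference of the noise-free curve peaks exactly at the elbow."""
        curve = make_loss_curve(20, 0.012, 0.001, 0.0, 60, seed=0)
        second = np.abs(np.diff(curve.validation_loss, 2))
        assert int(np.argmax(second)) + 1 == 20

    def test_equal_rates_flagged_degenerate(self):
        with pytest.raises(NoElbowError):
            make_loss_curve(10, 0.01, 0.01, 0.0, 40)

    def test_same_seed_identical_curves(self):
        c1 = make_loss_curve(10, 0.012, 0.001, 0.05, 40, seed=3)
        c2 = make_loss_curve(10, 0.012, 0.001, 0.05, 40, seed=3)
        assert np.array_equal(c1.validation_loss, c2.validation_loss)

    def test_expectation_monotone_decreasing(self):
        c = make_loss_curve(15, 0.012, 0.002, 0.0, 50)
        assert (np.diff(c.validation_loss) < 0).all()


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path, tiny_a2c_study):
        out = save_study(tiny_a2c_study, tmp_path / "study")
        clips, truth, manifest = load_study(out)
        assert len(clips) == 1 and len(clips[0]) == 16
        assert manifest["ef_target"] == pytest.approx(0.6)
        orig = tiny_a2c_study.truth_masks["video0"][0][Chamber.LV]
        assert np.array_equal(truth["video0"][0][Chamber.LV], orig)
        # 8-bit image round trip loses at most half a gray level
        reread = clips[0].frames[0].pixels
        assert np.abs(reread - tiny_a2c_study.clips[0].frames[0].pixels).max() < 0.01
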