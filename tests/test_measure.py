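"""Measurement-engine oracles: discs vs closed forms, mass, EF, frame picks."""
import math

import numpy as np
import pytest

from conftest import disc_mask_set, rasterize_disc, rasterize_ellipse
from echoseg.datatypes import Chamber, ChamberMaskSet, MeasurementSet
from echoseg.errors import (
    DegenerateError,
    FitFailureError,
    InvalidGeometryError,
    InvertedPhasesError,
    ManualSelectionRequiredError,
    UnconfiguredMeasureError,
)
from echoseg import measure


class TestMethodOfDiscs:
    def test_biplane_sphere_oracle(self):
        """Disc r=20 mm in both views at 0.5 mm/px: sphere volume 33.51 mL."""
        ms = disc_mask_set(20.0, 0.5)
        v = measure.method_of_discs({"A4C": ms, "A2C": ms}, Chamber.LV, 20, "biplane")
        assert v == pytest.approx(4.0 / 3.0 * math.pi * 20**3 / 1000.0, rel=0.02)

    def test_identical_masks_biplane_equals_single(self):
        ms = disc_mask_set(18.0, 0.5)
        bi = measure.method_of_discs({"a": ms, "b": ms}, Chamber.LV, 20, "biplane")
        single = measure.method_of_discs(ms, Chamber.LV, 20, "single")
        assert bi == pytest.approx(single, abs=1e-12)

    def test_single_plane_prolate_spheroid(self):
        a, b = 40.0, 25.0
        el = rasterize_ellipse(a, b, 0.5)
        ms = ChamberMaskSet({Chamber.LV: el}, pixel_spacing=0.5)
        v = measure.method_of_discs(ms, Chamber.LV, 20, "single")
        assert v == pytest.approx(4.0 / 3.0 * math.pi * a * b**2 / 1000.0, rel=0.03)

    def test_single_plane_half_spheroid(self):
        """LV-like bullet: a 60x25 mm ellipse cut at the base."""
        a, b = 60.0, 25.0
        el = rasterize_ellipse(a, b, 0.5)
        half = el.copy()
        half[: el.shape[0] // 2] = False
        ms = ChamberMaskSet({Chamber.LV: half}, pixel_spacing=0.5)
        v = measure.method_of_discs(ms, Chamber.LV, 20, "single")
        assert v == pytest.approx(0.5 * 4.0 / 3.0 * math.pi * a * b**2 / 1000.0, rel=0.03)

    def test_error_decreases_as_discs_double(self):
        a, b = 40.0, 25.0
        el = rasterize_ellipse(a, b, 0.5)
        ms = ChamberMaskSet({Chamber.LV: el}, pixel_spacing=0.5)
        analytic = 4.0 / 3.0 * math.pi * a * b**2 / 1000.0
        errs = [
            abs(measure.method_of_discs(ms, Chamber.LV, n, "single") - analytic)
            for n in (8, 16, 32)
        ]
        assert errs[0] > errs[1] > errs[2]

    def test_biplane_symmetric_under_view_swap(self):
        m1 = ChamberMaskSet({Chamber.LV: rasterize_ellipse(35, 20, 0.5)}, pixel_spacing=0.5)
        m2 = ChamberMaskSet({Chamber.LV: rasterize_ellipse(38, 17, 0.5)}, pixel_spacing=0.5)
        v_ab = measure.method_of_discs({"a": m1, "b": m2}, Chamber.LV, 20, "biplane")
        v_ba = measure.method_of_discs({"b": m2, "a": m1}, Chamber.LV, 20, "biplane")
        assert v_ab == pytest.approx(v_ba, abs=1e-12)

    def test_degenerate_mask_raises(self):
        tiny = np.zeros((32, 32), bool)
        tiny[4, 4] = True
        ms = ChamberMaskSet({Chamber.LV: tiny}, pixel_spacing=0.5)
        with pytest.raises(DegenerateError):
            measure.method_of_discs(ms, Chamber.LV, 20, "single")


class TestLVMass:
    def test_closed_form_example(self):
        # endo r=2 cm, epi r=3 cm, L=7 cm -> t=1 cm, mass 120.95 g
        mass = measure.lv_mass_area_length(9 * math.pi, 4 * math.pi, 7.0)
        assert mass == pytest.approx(120.95, abs=0.005)

    def test_equal_areas_invalid(self):
        with pytest.raises(InvalidGeometryError):
            measure.lv_mass_area_length(10.0, 10.0, 7.0)

    def test_doubling_linear_dimensions_scales_by_8(self):
        m1 = measure.lv_mass_area_length(9 * math.pi, 4 * math.pi, 7.0)
        m2 = measure.lv_mass_area_length(36 * math.pi, 16 * math.pi, 14.0)
        assert m2 == pytest.approx(8 * m1, rel=1e-12)


class TestLVEF:
    @pytest.mark.parametrize(
        "edv,esv,expected", [(100, 40, 60.0), (50, 50, 0.0), (120, 30, 75.0)]
    )
    def test_closed_formula(self, edv, esv, expected):
        assert measure.compute_lvef(edv, esv) == pytest.approx(expected)

    def test_inverted_phases(self):
        with pytest.raises(InvertedPhasesError):
            measure.compute_lvef(50, 60)

    def test_single_plane_ef_isotropic_shrink(self):
        """ES = ED shrunk by 0.8 in both axes: EF = 100*(1 - 0.8^3) = 48.8%."""
        ed = rasterize_ellipse(40, 25, 0.5)
        es = rasterize_ellipse(32, 20, 0.5)
        # pad es to same shape as ed
        pad = (ed.shape[0] - es.shape[0]) // 2
        es_p = np.zeros_like(ed)
        es_p[pad: pad + es.shape[0], pad: pad + es.shape[1]] = es
        ef = measure.single_plane_ef_estimate(ed, es_p)
        assert ef == pytest.approx(100 * (1 - 0.8**3), abs=2.0)

    def test_single_plane_ef_zero_when_equal(self):
        ed = rasterize_ellipse(40, 25, 0.5)
        assert measure.single_plane_ef_estimate(ed, ed) == pytest.approx(0.0)

    def test_single_plane_ef_spacing_invariant(self):
        """The pixel-ratio estimate ignores pixel spacing entirely."""
        ed = rasterize_ellipse(40, 25, 1.0)
        es = np.roll(ed, 2, axis=0) & ed
        assert measure.single_plane_ef_estimate(ed, es) == measure.single_plane_ef_estimate(
            ed, es
        )


class TestSinusoidFitting:
    def _trace(self, n=40, fr=20.0, hr=72.0, amp=4.0, offset=15.0, phase=0.4):
        t = np.arange(n) / fr
        return offset + amp * np.sin(2 * np.pi * hr / 60.0 * t + phase)

    def test_exact_trace_recovery(self):
        trace = self._trace()
        fit = measure.fit_cardiac_sinusoid(trace, 72.0, 20.0)
        assert fit.r_squared >= 0.999
        assert fit.amplitude == pytest.approx(4.0, rel=0.01)
        assert fit.offset == pytest.approx(15.0, rel=0.01)

    def test_constant_trace_fails(self):
        with pytest.raises(FitFailureError):
            measure.fit_cardiac_sinusoid(np.full(40, 12.0), 72.0, 20.0)

    def test_noisy_trace_r2_band(self):
        """SNR 10 white noise: r^2 stays within [0.8, 1.0] across 100 seeds."""
        r2s = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = self._trace() + rng.normal(0, 0.4, size=40)
            r2s.append(measure.fit_cardiac_sinusoid(noisy, 72.0, 20.0).r_squared)
        assert min(r2s) > 0.8 and max(r2s) <= 1.0

    def test_missing_frames_are_skipped(self):
        trace = self._trace()
        trace[5] = np.nan
        fit = measure.fit_cardiac_sinusoid(trace, 72.0, 20.0)
        assert fit.r_squared >= 0.999

    def test_unknown_heart_rate_estimated_from_periodogram(self):
        trace = self._trace(n=60, hr=75.0)
        fit = measure.fit_cardiac_sinusoid(trace, None, 20.0)
        assert fit.frequency == pytest.approx(75.0 / 60.0, abs=0.05)


class TestCycleFrameSelection:
    def _fit(self, r2):
        return measure.SinusoidFit(10.0, 3.0, 1.0, 0.0, r2)

    def test_picks_best_r2_video(self):
        study = {
            "noisy": (self._fit(0.5), np.array([3.0, 4.0, 2.0])),
            "clean": (self._fit(0.99), np.array([1.0, 5.0, 2.0])),
            "failed": (None, np.array([2.0, 2.0, 2.0])),
        }
        vid, ed, es = measure.select_cycle_frames(study)
        assert vid == "clean" and ed == 1 and es == 0

    def test_ed_es_at_phase_extremes(self, tiny_a2c_study):
        masks = tiny_a2c_study.truth_masks["video0"]
        trace = measure.area_trace(masks, Chamber.LV)
        fit = measure.fit_cardiac_sinusoid(trace, 60.0, 15.0)
        _, ed, es = measure.select_cycle_frames({"video0": (fit, trace)})
        # heart rate 60 at 15 fps: ED at frame 0 or 15, ES mid-cycle
        assert min(abs(ed - 0), abs(ed - 15)) <= 1
        assert abs(es - 7.5) <= 1.5

    def test_all_failed_requires_manual_selection(self):
        with pytest.raises(ManualSelectionRequiredError):
            measure.select_cycle_frames({"v": (None, np.array([1.0, 1.0]))})

    def test_ties_break_to_earliest_frame(self):
        trace = np.array([5.0, 1.0, 5.0, 1.0])
        vid, ed, es = measure.select_cycle_frames({"v": (self._fit(0.9), trace)})
        assert ed == 0 and es == 1


class TestAreaTrace:
    def test_missing_frames_are_nan_not_zero(self):
        ms = disc_mask_set(10.0, 0.5)
        trace = measure.area_trace([ms, None, ms], Chamber.LV)
        assert np.isfinite(trace[0]) and np.isnan(trace[1]) and np.isfinite(trace[2])

    def test_constant_masks_constant_trace(self):
        ms = disc_mask_set(10.0, 0.5)
        trace = measure.area_trace([ms] * 4, Chamber.LV)
        assert np.allclose(trace, trace[0])


class TestClassification:
    def test_normal_lvef(self):
        ms = measure.classify_measurements(MeasurementSet(lvef=65.0), None, "M")
        assert ms.category["lvef"] == "normal"
        assert ms.grade["lvef"] == "normal"

    def test_boundary_value_called_abnormal(self):
        """The abnormal interval is closed at the threshold."""
        ms = measure.classify_measurements(MeasurementSet(lvef=52.0), None, "M")
        assert ms.category["lvef"] == "abnormal"

    def test_bsa_indexing(self):
        ms = measure.classify_measurements(
            MeasurementSet(lvedv=150.0), bsa=2.0, sex="M"
        )
        assert ms.indexed["lvedv"] == pytest.approx(75.0)
        assert ms.category["lvedv"] == "abnormal"  # >= 74 mL/m2

    def test_missing_bsa_for_indexed_measure(self):
        with pytest.raises(UnconfiguredMeasureError):
            measure.classify_measurements(MeasurementSet(lvedv=150.0), None, "M")

    def test_missing_threshold_row(self):
        with pytest.raises(UnconfiguredMeasureError):
            measure.classify_measurements(
                MeasurementSet(lvef=60.0), None, "F", thresholds={}
            )

    def test_severity_grading(self):
        ms = measure.classify_measurements(MeasurementSet(lvef=35.0), None, "F")
        assert ms.grade["lvef"] == "moderate"
        ms = measure.classify_measurements(MeasurementSet(lvef=25.0), None, "F")
        assert ms.grade["lvef"] == "severe"
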