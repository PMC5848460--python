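import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from magrule.morphometry import (
    ROI,
    CellMeasurement,
    MeasureConfig,
    ProfileMeasurement,
    aggregate_cell,
    extract_profile,
    measure_intensity,
    measure_profile,
    measure_specimen,
    measure_width,
    place_rois,
    ring_completeness,
    summarize_specimen,
)
from magrule.optics import ScoreCategory
from magrule.stain import dab_intensity_pct
from magrule.synth import CellTruth, render_specimen

from conftest import single_cell_config, box_gauss_fwhm

STEP_UM = 0.25 / 5.11  # default sampling step


def cell(radius=7.0, completeness=1.0, arc_start=0.0):
    return CellTruth(0, 15.0, 15.0, radius, 1.0, 0.8, completeness, arc_start)


class TestPlaceRois:
    def test_four_rois_quarter_spacing(self):
        rois = place_rois(cell(), k=4)
        angles = sorted(
            math.atan2(
                (r.y1_um + r.y2_um) / 2 - 15.0, (r.x1_um + r.x2_um) / 2 - 15.0
            )
            % (2 * math.pi)
            for r in rois
        )
        diffs = np.diff(angles)
        assert np.allclose(diffs, math.pi / 2, atol=1e-9)

    def test_single_roi_through_east_point(self):
        (roi,) = place_rois(cell(radius=7.0), k=1, length_um=4.0)
        assert roi.x1_um == pytest.approx(15.0 + 7.0 - 2.0)
        assert roi.x2_um == pytest.approx(15.0 + 7.0 + 2.0)
        assert roi.y1_um == pytest.approx(15.0)
        assert roi.y2_um == pytest.approx(15.0)

    def test_partial_ring_confines_rois(self, rng):
        c = cell(completeness=0.5, arc_start=0.3)
        for _ in range(10):
            rois = place_rois(c, k=4, rng=rng)
            for r in rois:
                mx = (r.x1_um + r.x2_um) / 2 - 15.0
                my = (r.y1_um + r.y2_um) / 2 - 15.0
                rel = (math.atan2(my, mx) - 0.3) % (2 * math.pi)
                assert rel <= 0.5 * 2 * math.pi + 1e-9

    def test_rois_centered_on_membrane(self):
        rois = place_rois(cell(radius=8.0), k=3, length_um=6.0)
        for r in rois:
            mx = (r.x1_um + r.x2_um) / 2
            my = (r.y1_um + r.y2_um) / 2
            assert math.hypot(mx - 15.0, my - 15.0) == pytest.approx(8.0)
            assert r.length_um == pytest.approx(6.0)

    def test_jitter_is_seeded(self):
        r1 = place_rois(cell(), k=4, rng=np.random.default_rng(3))
        r2 = place_rois(cell(), k=4, rng=np.random.default_rng(3))
        assert r1 == r2

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            place_rois(cell(), k=0)

    def test_degenerate_roi_rejected(self):
        with pytest.raises(ValueError):
            ROI(0, 1.0, 1.0, 1.0, 1.0)


class TestExtractProfile:
    def test_background_is_zero(self):
        dab = np.zeros((100, 100))
        roi = ROI(0, 2.0, 5.0, 8.0, 5.0)
        dist, od = extract_profile(dab, roi, pixel_scale=5.11)
        assert np.all(od == 0.0)
        assert dist[0] == 0.0
        assert dist[-1] == pytest.approx(roi.length_um)

    def test_out_of_bounds_names_cell(self):
        dab = np.zeros((50, 50))
        roi = ROI(7, -5.0, 1.0, 5.0, 1.0)
        with pytest.raises(ValueError, match="cell 7"):
            extract_profile(dab, roi, pixel_scale=5.11)

    def test_unblurred_band_is_box(self):
        # sharp rendering (psf 0, high supersampling): the radial profile is
        # a box of the true width, up to one sample step + raster error
        cfg = single_cell_config(
            1.2, psf_sigma_um=0.0, noise_sd=0.0, pixel_scale=20.0, supersample=8
        )
        img, truths = render_specimen(cfg)
        from magrule.stain import separate_stains

        dab = separate_stains(img).channel("dab")
        (roi,) = place_rois(truths[0], k=1, length_um=4.0)
        dist, od = extract_profile(dab, roi, pixel_scale=20.0)
        step = 0.25 / 20.0
        w = measure_width(od, step)
        assert w == pytest.approx(1.2, abs=step + 1.0 / 20.0)
        assert od.max() == pytest.approx(truths[0].amplitude_od, abs=0.02)

    def test_too_short_profile(self):
        dab = np.zeros((50, 50))
        roi = ROI(0, 5.0, 5.0, 5.05, 5.0)
        with pytest.raises(ValueError):
            extract_profile(dab, roi, pixel_scale=5.11)


class TestMeasureWidth:
    def test_ideal_box(self):
        od = np.zeros(60)
        od[20:30] = 0.8  # 10 samples wide
        w = measure_width(od, STEP_UM)
        assert w == pytest.approx(10 * STEP_UM, rel=1e-9)

    def test_gaussian_profile_closed_form(self):
        s = 8.0  # samples
        x = np.arange(200.0)
        od = 0.6 * np.exp(-0.5 * ((x - 100) / s) ** 2)
        w = measure_width(od, STEP_UM)
        assert w == pytest.approx(2.3548 * s * STEP_UM, rel=0.01)

    def test_flat_zero_invalid(self):
        assert measure_width(np.zeros(50), STEP_UM) is None

    def test_below_min_peak_invalid(self):
        od = np.zeros(50)
        od[25] = 0.04
        assert measure_width(od, STEP_UM, min_peak_od=0.05) is None

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            measure_width(np.zeros(4), STEP_UM)

    def test_truncated_band_invalid(self):
        od = np.linspace(0, 1, 50)  # no right crossing
        assert measure_width(od, STEP_UM) is None

    def test_psf_correction(self):
        od = np.zeros(80)
        od[30:50] = 1.0
        raw = measure_width(od, STEP_UM)
        corrected = measure_width(
            od, STEP_UM, psf_correction=True, psf_sigma_um=0.10
        )
        assert corrected == pytest.approx(
            math.sqrt(raw**2 - (2.3548 * 0.10) ** 2)
        )

    @given(
        width=st.integers(6, 30),
        scale=st.floats(0.1, 5.0),
        start=st.integers(5, 40),
    )
    @settings(max_examples=50)
    def test_reversal_and_scale_invariance(self, width, scale, start):
        od = np.zeros(100)
        od[start : start + width] = 0.5
        od[start + width // 2] = 0.7  # make the peak unambiguous
        w = measure_width(od, STEP_UM)
        assert measure_width(od[::-1], STEP_UM) == pytest.approx(w, rel=1e-9)
        assert measure_width(scale * od, STEP_UM) == pytest.approx(w, rel=1e-9)


class TestMeasureIntensity:
    def test_band_od_one(self):
        od = np.zeros(60)
        od[20:30] = 1.0
        pct = measure_intensity(od, STEP_UM)
        assert pct == pytest.approx(dab_intensity_pct([1.0]))

    def test_monotone_in_amplitude(self):
        od = np.zeros(60)
        od[20:30] = 0.5
        assert measure_intensity(2 * od, STEP_UM) >= measure_intensity(od, STEP_UM)

    def test_invalid_profile_gives_none(self):
        assert measure_intensity(np.zeros(50), STEP_UM) is None

    def test_measure_profile_bundle(self):
        od = np.zeros(60)
        od[20:30] = 1.0
        pm = measure_profile(od, STEP_UM)
        assert pm.valid
        assert pm.width_um == pytest.approx(10 * STEP_UM)
        assert pm.peak_od == pytest.approx(1.0)
        pm0 = measure_profile(np.zeros(60), STEP_UM)
        assert not pm0.valid and math.isnan(pm0.width_um)


class TestAggregation:
    def pm(self, w, i=50.0):
        return ProfileMeasurement(w, i, 0.5, True)

    def test_mean_of_four(self):
        cm = aggregate_cell([self.pm(1.0)] * 4, 0)
        assert cm.mean_width_um == pytest.approx(1.0)
        assert cm.n_valid_rois == 4

    def test_mean_over_valid_only(self):
        profiles = [self.pm(0.8), self.pm(1.0), self.pm(1.2), ProfileMeasurement.invalid()]
        cm = aggregate_cell(profiles, 1)
        assert cm.mean_width_um == pytest.approx(1.0)
        assert cm.n_valid_rois == 3

    def test_all_invalid(self):
        cm = aggregate_cell([ProfileMeasurement.invalid()] * 4, 2)
        assert cm.n_valid_rois == 0
        assert math.isnan(cm.mean_width_um)

    def test_specimen_three_plus(self):
        cells = [CellMeasurement(i, 2.14, 80.0, 4) for i in range(10)]
        s = summarize_specimen(cells, "spec")
        assert s.assigned_score is ScoreCategory.THREE_PLUS
        assert s.mean_width_um == pytest.approx(2.14)

    def test_specimen_all_absent_scores_zero(self):
        cells = [CellMeasurement(i, float("nan"), float("nan"), 0) for i in range(10)]
        s = summarize_specimen(cells, "spec")
        assert s.assigned_score is ScoreCategory.ZERO
        assert math.isnan(s.mean_width_um)

    def test_single_cell_sd_undefined(self):
        s = summarize_specimen([CellMeasurement(0, 1.0, 50.0, 4)], "spec")
        assert math.isnan(s.sd_width_um)
        assert s.mean_width_um == pytest.approx(1.0)

    def test_empty_cell_list_rejected(self):
        with pytest.raises(ValueError):
            summarize_specimen([], "spec")


class TestRingCompleteness:
    def render(self, completeness):
        cfg = single_cell_config(
            1.5, noise_sd=0.0, completeness=completeness, canvas_um=30.0
        )
        img, truths = render_specimen(cfg)
        from magrule.stain import separate_stains

        return separate_stains(img).channel("dab"), truths[0]

    def test_full_ring(self):
        dab, truth = self.render(1.0)
        assert ring_completeness(truth, dab, 5.11) == pytest.approx(1.0)

    def test_half_ring(self):
        dab, truth = self.render(0.5)
        assert ring_completeness(truth, dab, 5.11) == pytest.approx(0.5, abs=0.02)

    def test_unstained_cell(self):
        dab = np.zeros((160, 160))
        truth = CellTruth(0, 15.0, 15.0, 7.0, 1.0, 0.8, 1.0)
        assert ring_completeness(truth, dab, 5.11) == 0.0


class TestEndToEnd:
    @pytest.mark.parametrize("width", [0.4, 0.8, 1.5, 2.0, 3.0])
    def test_width_recovery_against_oracle(self, width):
        cfg = single_cell_config(width, psf_sigma_um=0.10, noise_sd=0.0)
        img, truths = render_specimen(cfg)
        _, summary, _ = measure_specimen(img, truths, "S", roi_seed=1)
        assert summary.mean_width_um == pytest.approx(
            box_gauss_fwhm(width, 0.10), abs=0.1
        )

    def test_measure_specimen_tables(self):
        cfg = single_cell_config(1.0, seed=5)
        img, truths = render_specimen(cfg)
        cms, summary, profiles = measure_specimen(img, truths, "S0", roi_seed=5)
        assert len(cms) == 1
        assert len(profiles) == 4
        assert set(profiles.columns) >= {
            "specimen_id",
            "cell_id",
            "roi_index",
            "width_um",
            "intensity_pct",
            "valid",
        }
        assert summary.n_cells == 1
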