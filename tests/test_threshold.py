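"""Core percent-above-threshold algorithm: peaks, interpolation, integration."""

from dataclasses import replace

import numpy as np
import pytest

from gelquant import score_gel
from gelquant.errors import (
    BracketingError,
    GelQuantError,
    LadderCallError,
    ParameterError,
    ThresholdError,
)
from gelquant.lanes import IntensityProfile, LaneBox
from gelquant.synthetic import SyntheticGelSpec, default_lane_boxes, random_gel_spec, render_gel
from gelquant.threshold import (
    ThresholdSpec,
    apex_of_threshold_band,
    close_profile,
    find_band_peaks,
    integrate_regions,
    mask_artifact,
    percent_above_threshold,
    threshold_row_for_lane,
)


def make_profile(values, **kwargs):
    values = np.asarray(values, dtype=float)
    box = LaneBox(center_col=20.0, width=10, row_top=0, row_bottom=len(values))
    return IntensityProfile(values=values, lane=box, **kwargs)


def gaussian_bands(length, centers, heights, sigma=3.0):
    rows = np.arange(length, dtype=float)
    out = np.zeros(length)
    for c, h in zip(centers, heights):
        out += h * np.exp(-0.5 * ((rows - c) / sigma) ** 2)
    return out


class TestFindBandPeaks:
    def test_synthetic_ladder_fully_assigned_within_2px(
        self, default_spec, scored_default
    ):
        for label, peaks in scored_default.ladder_peaks.items():
            assigned = {p.assigned_size: p.row for p in peaks if p.assigned_size}
            assert set(assigned) == set(default_spec.ladder.band_sizes)
            box_top = scored_default.ladder_profiles[label].lane.row_top
            for size, row in assigned.items():
                assert abs(box_top + row - default_spec.band_row(size)) <= 2.0

    def test_single_peak_is_a_ladder_call_error(self, ladder):
        prof = make_profile(gaussian_bands(200, [100], [0.5]))
        with pytest.raises(LadderCallError):
            find_band_peaks(prof, ladder)

    def test_empty_profile_is_a_ladder_call_error(self, ladder):
        with pytest.raises(LadderCallError):
            find_band_peaks(make_profile(np.zeros(100)), ladder)

    def test_equal_height_spurious_peak_loses_to_expected_position(self, ladder):
        """Of two equal maxima near one band, the log-linear-consistent one wins."""
        a, b = 700.0, -150.0
        true_rows = [a + b * np.log10(s) for s in ladder.band_sizes]
        heights = [0.5] * 7
        values = gaussian_bands(360, true_rows, heights)
        # an equal-height spur 14 px from the 6557 bp band's true row
        spur_row = true_rows[2] + 14.0
        values += gaussian_bands(360, [spur_row], [0.5])
        peaks = find_band_peaks(make_profile(values), ladder)
        row_6557 = next(p.row for p in peaks if p.assigned_size == 6557)
        assert abs(row_6557 - true_rows[2]) < 2.0


class TestApexAndInterpolation:
    def test_apex_lookup_and_missing_band(self, ladder, scored_default):
        peaks = next(iter(scored_default.ladder_peaks.values()))
        row = apex_of_threshold_band(peaks, 9416)
        assert row > 0
        unassigned = [replace(p, assigned_size=None) for p in peaks]
        with pytest.raises(ThresholdError, match="9416"):
            apex_of_threshold_band(unassigned, 9416, "ladderL")

    def test_level_gel_gives_constant_threshold(self):
        spec = ThresholdSpec("hindiii", 9416, 210.0, 210.0, 40.0, 400.0)
        for col in (40.0, 150.0, 400.0):
            assert threshold_row_for_lane(spec, col) == 210.0

    def test_midpoint_interpolation(self):
        spec = ThresholdSpec("hindiii", 9416, 200.0, 220.0, 100.0, 300.0)
        assert threshold_row_for_lane(spec, 200.0) == pytest.approx(210.0)

    def test_outside_bracketing_ladders_rejected(self):
        spec = ThresholdSpec("hindiii", 9416, 200.0, 220.0, 100.0, 300.0)
        with pytest.raises(BracketingError):
            threshold_row_for_lane(spec, 50.0)

    def test_skew_compensated_threshold_within_1px(self, ladder):
        spec = SyntheticGelSpec(seed=21, skew_deg=1.0)
        gel, truth = render_gel(spec)
        scored = score_gel(gel, default_lane_boxes(spec), ladder, 9416)
        for q in scored.quantifications:
            idx = truth.lane_labels.index(q.label)
            assert abs(q.threshold_row - truth.band_rows[9416][idx]) <= 1.0


class TestCloseAndMask:
    def test_profile_ending_at_zero_closes_silently(self):
        prof = close_profile(make_profile(gaussian_bands(100, [50], [0.5])))
        assert prof.closed and not prof.closure_applied

    def test_open_profile_closure_recorded_area_unchanged(self):
        values = np.linspace(0.5, 0.3, 100)
        prof = make_profile(values)
        closed = close_profile(prof)
        assert closed.closed and closed.closure_applied
        assert np.array_equal(closed.values, values)  # vertical drop adds no area

    def test_masking_flat_segment_is_identity(self):
        prof = make_profile(np.full(50, 0.2))
        masked = mask_artifact(prof, 10, 30)
        assert np.allclose(masked.values, 0.2)
        assert masked.mask_segments == ((10, 30),)

    def test_masking_triangular_spur_removes_its_area(self):
        base = np.full(101, 0.1)
        spur = np.zeros(101)
        spur[40:61] = np.concatenate([np.linspace(0, 0.3, 11), np.linspace(0.3, 0, 11)[1:]])
        prof = close_profile(make_profile(base + spur))
        masked = mask_artifact(prof, 38, 62)
        area_before = np.trapezoid(prof.values)
        area_after = np.trapezoid(masked.values)
        spur_area = np.trapezoid(spur)
        assert area_before - area_after == pytest.approx(spur_area, abs=1e-12)

    def test_invalid_mask_rows_rejected(self):
        prof = make_profile(np.full(50, 0.2))
        for bad in [(30, 10), (-1, 10), (10, 60)]:
            with pytest.raises(ParameterError):
                mask_artifact(prof, *bad)

    def test_masked_speck_recovers_clean_score(self, ladder):
        """A dark gel flaw is neutralized by the chord mask."""
        from gelquant.synthetic import Speck

        clean_spec = SyntheticGelSpec(seed=7)
        speck_spec = replace(
            clean_spec, specks=(Speck(row=250.0, col=175.0, amplitude=0.35, sigma=3.0),)
        )
        g_clean, _ = render_gel(clean_spec)
        g_speck, _ = render_gel(speck_spec)
        boxes = default_lane_boxes(clean_spec)
        pct_clean = score_gel(g_clean, boxes, ladder, 9416).percent("S2")
        pct_speck = score_gel(g_speck, boxes, ladder, 9416).percent("S2")
        pct_masked = score_gel(
            g_speck, boxes, ladder, 9416, masks={"S2": [(238, 262)]}
        ).percent("S2")
        assert abs(pct_speck - pct_clean) > abs(pct_masked - pct_clean)
        assert pct_masked == pytest.approx(pct_clean, abs=1.0)


class TestIntegration:
    def test_constant_profile_splits_evenly_at_midrow(self):
        prof = close_profile(make_profile(np.full(101, 0.4)))
        above, below = integrate_regions(prof, 50.0)
        assert above == pytest.approx(below, abs=0.4)  # within one trapezoid cell

    def test_all_intensity_above_threshold(self):
        values = np.zeros(100)
        values[:40] = 0.5
        values[40] = 0.0
        prof = close_profile(make_profile(values))
        above, below = integrate_regions(prof, 60.0)
        assert below == 0.0 and above > 0

    def test_conservation_is_exact(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            values = rng.random(80)
            prof = close_profile(make_profile(values))
            t = float(rng.uniform(0, 79))
            above, below = integrate_regions(prof, t)
            assert above + below == pytest.approx(float(np.trapezoid(values)), abs=1e-9)

    def test_unclosed_profile_and_bad_threshold_rejected(self):
        prof = make_profile(np.full(50, 0.2))
        with pytest.raises(ParameterError):
            integrate_regions(prof, 10.0)
        with pytest.raises(ParameterError):
            integrate_regions(close_profile(prof), 99.0)

    def test_trapezoid_matches_pixel_sum_oracle(self, ladder):
        """Brute-force rectangular pixel sums over the raw lane boxes."""
        checked = 0
        for seed in range(5):
            spec = random_gel_spec(seed + 300)
            gel, _ = render_gel(spec)
            scored = score_gel(gel, default_lane_boxes(spec), ladder, 9416)
            raster = scored.gel.data
            for q in scored.quantifications:
                box = scored.sample_profiles[q.label].lane
                block = raster[box.row_top:box.row_bottom, box.col_start:box.col_stop]
                rows = np.arange(block.shape[0]) + box.row_top
                per_row = block.sum(axis=1) / box.width
                rect_above = float(per_row[rows <= q.threshold_row].sum())
                rect_below = float(per_row[rows > q.threshold_row].sum())
                total = q.area_above + q.area_below
                assert abs(q.area_above - rect_above) <= 0.005 * total
                assert abs(q.area_below - rect_below) <= 0.005 * total
                checked += 1
        assert checked == 20


class TestPercent:
    def test_direct_ratio_and_bounds(self):
        assert percent_above_threshold(72.0, 28.0) == pytest.approx(72.0)
        assert percent_above_threshold(0.0, 5.0) == 0.0
        assert percent_above_threshold(5.0, 0.0) == 100.0

    def test_negative_area_is_invariant_violation(self):
        with pytest.raises(GelQuantError):
            percent_above_threshold(-1.0, 5.0)

    def test_empty_lane_returns_none_with_warning(self):
        with pytest.warns(UserWarning, match="empty lane"):
            assert percent_above_threshold(0.0, 0.0) is None
        with pytest.warns(UserWarning, match="empty lane"):
            assert percent_above_threshold(1e-8, 1e-8, profile_length=360) is None


class TestScoreGel:
    def test_recovers_known_fractions_within_3_points(
        self, default_spec, default_render, default_boxes, ladder, scored_default
    ):
        _, truth = default_render
        assert len(scored_default.quantifications) == 4
        for q in scored_default.quantifications:
            assert q.percent_above == pytest.approx(
                truth.percent_above(9416, q.label), abs=3.0
            )

    def test_scoring_is_deterministic(self, default_render, default_boxes, ladder):
        gel, _ = default_render
        s1 = score_gel(gel, default_boxes, ladder, 9416)
        s2 = score_gel(gel, default_boxes, ladder, 9416)
        assert s1.quantifications == s2.quantifications
        assert s1.threshold_spec == s2.threshold_spec

    def test_unbracketed_sample_rejected(self, default_render, default_boxes, ladder):
        gel, _ = default_render
        stray = LaneBox(
            center_col=20.0,
            width=10,
            row_top=default_boxes[0].row_top,
            row_bottom=default_boxes[0].row_bottom,
            role="sample",
            label="stray",
        )
        with pytest.raises(BracketingError):
            score_gel(gel, list(default_boxes) + [stray], ladder, 9416)

    def test_threshold_must_be_a_ladder_band(self, default_render, default_boxes, ladder):
        gel, _ = default_render
        with pytest.raises(ThresholdError):
            score_gel(gel, default_boxes, ladder, 9000)

    def test_scale_invariance_of_percentages(self, scored_default, default_boxes, ladder):
        base = scored_default
        scaled_gel = replace(base.gel, data=0.37 * base.gel.data)
        scaled = score_gel(scaled_gel, default_boxes, ladder, 9416)
        for q0, q1 in zip(base.quantifications, scaled.quantifications):
            assert q1.percent_above == pytest.approx(q0.percent_above, abs=1e-9)

    def test_larger_threshold_band_never_increases_percent(
        self, default_render, default_boxes, ladder, scored_default
    ):
        gel, _ = default_render
        s23 = score_gel(gel, default_boxes, ladder, 23130)
        for q9, q23 in zip(scored_default.quantifications, s23.quantifications):
            assert q23.percent_above <= q9.percent_above + 1e-9

    def test_dilution_series_picks_clearest_ladder(self, ladder):
        """With extra dilute ladder lanes, the scorer still finds the threshold."""
        spec = SyntheticGelSpec(
            seed=13,
            ladder_cols=(40.0, 70.0, 370.0, 400.0),
            ladder_dilutions=(1.0, 0.05, 0.05, 1.0),
            sample_cols=(140.0, 200.0, 260.0, 320.0),
        )
        gel, truth = render_gel(spec)
        boxes = default_lane_boxes(spec)
        scored = score_gel(gel, boxes, ladder, 9416)
        assert set(scored.ladder_profiles) == {"ladderL1", "ladderR2"}
        for q in scored.quantifications:
            assert q.percent_above == pytest.approx(
                truth.percent_above(9416, q.label), abs=3.0
            )
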