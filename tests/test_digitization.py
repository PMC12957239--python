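"""Digitization pipeline: binarization, linear mapping, extraction, splicing.

The renderer's exact trace-pixel mask and the simulated signals serve as the
ground-truth oracles for the round-trip properties.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctgvision.chart_synthesis import (ChartLayout, SignalParams,
                                       make_dataset, render_chart,
                                       simulate_fhr, simulate_uc)
from ctgvision.digitization import (BinaryMask, RegionSpec, binarize,
                                    detect_region_boxes, digitize_chart,
                                    extract_trace, pixel_to_value,
                                    splice_segments, standardize_to_input)
from ctgvision.signals import TraceSignal


class TestBinarize:
    def test_below_threshold_is_background(self):
        mask = binarize(np.full((4, 4), 64, dtype=np.uint8))
        assert not mask.pixels.any()

    def test_boundary_pixel_65_is_foreground(self):
        img = np.zeros((3, 3), dtype=np.uint8)
        img[1, 1] = 65
        mask = binarize(img)
        assert mask.pixels[1, 1] and mask.pixels.sum() == 1

    def test_rgb_converted_via_luminance(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[0, 0] = (255, 255, 255)
        assert binarize(img).pixels[0, 0]

    def test_recovers_renderer_mask_exactly(self, wiggly_chart):
        chart, truth = wiggly_chart
        mask = binarize(chart)
        assert np.array_equal(mask.pixels, truth.trace_pixel_mask)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            binarize(np.empty((0, 0), dtype=np.uint8))


FHR_REGION = RegionSpec(box=(10, 20, 100, 151), channel="fhr",
                        segment_index=0)


class TestPixelToValue:
    def test_bottom_row_maps_to_vmin(self):
        assert pixel_to_value(20 + 150, FHR_REGION) == pytest.approx(60.0)

    def test_top_row_maps_to_vmax(self):
        assert pixel_to_value(20, FHR_REGION) == pytest.approx(210.0)

    def test_midpoint_row_maps_to_135(self):
        assert pixel_to_value(20 + 75, FHR_REGION) == pytest.approx(135.0)

    @given(st.integers(min_value=0, max_value=150))
    @settings(deadline=None, derandomize=True)
    def test_agrees_with_endpoint_interpolation(self, offset):
        # independent oracle: linear interpolation between the two endpoints
        y = 20 + offset
        expected = np.interp(y, [20, 170], [210.0, 60.0])
        assert pixel_to_value(y, FHR_REGION) == pytest.approx(expected,
                                                              abs=1e-9)

    @given(st.integers(min_value=0, max_value=140), st.integers(1, 10))
    @settings(deadline=None, derandomize=True)
    def test_monotone_row_shift(self, offset, k):
        # raising the trace by k rows raises the value by k * step
        y = 20 + offset
        step = 150.0 / 150  # (vmax - vmin) / (h - 1)
        lo = pixel_to_value(y + k, FHR_REGION)
        hi = pixel_to_value(y, FHR_REGION)
        assert hi - lo == pytest.approx(k * step, abs=1e-9)

    def test_row_outside_region_rejected(self):
        with pytest.raises(ValueError):
            pixel_to_value(19, FHR_REGION)
        with pytest.raises(ValueError):
            pixel_to_value(171, FHR_REGION)


class TestExtractTrace:
    def _mask_with_rows(self, rows_per_col, shape=(200, 100), x0=10, y0=20):
        pixels = np.zeros(shape, dtype=bool)
        for x, rows in rows_per_col.items():
            for r in rows:
                pixels[y0 + r, x0 + x] = True
        return BinaryMask(pixels)

    def test_median_row_of_a_thick_column(self):
        region = RegionSpec(box=(10, 20, 80, 151), channel="fhr",
                            segment_index=0)
        mask = self._mask_with_rows({x: (10, 11, 12) for x in range(80)})
        sig = extract_trace(mask, region, duration_s=80.0, out_rate=1.0)
        expected = pixel_to_value(20 + 11, region)
        assert np.allclose(sig.values, expected)

    def test_interior_gap_filled_linearly(self):
        region = RegionSpec(box=(0, 0, 8, 151), channel="fhr",
                            segment_index=0)
        pixels = np.zeros((151, 8), dtype=bool)
        rows = {0: 100, 1: 100, 2: 100, 6: 88, 7: 88}  # cols 3-5 empty
        for x, r in rows.items():
            pixels[r, x] = True
        sig = extract_trace(BinaryMask(pixels), region, duration_s=8.0,
                            out_rate=1.0)
        v2, v6 = sig.values[2], sig.values[6]
        assert not sig.valid[3:6].any()
        assert np.allclose(sig.values[3:6],
                           v2 + (v6 - v2) * np.array([1, 2, 3]) / 4)

    def test_edge_gaps_held_at_nearest_value(self):
        region = RegionSpec(box=(0, 0, 6, 151), channel="fhr",
                            segment_index=0)
        pixels = np.zeros((151, 6), dtype=bool)
        pixels[50, 2:] = True
        sig = extract_trace(BinaryMask(pixels), region, duration_s=6.0,
                            out_rate=1.0)
        assert np.allclose(sig.values, sig.values[2])
        assert not sig.valid[:2].any()

    def test_empty_region_rejected(self):
        region = RegionSpec(box=(0, 0, 6, 151), channel="fhr",
                            segment_index=0)
        with pytest.raises(ValueError, match="no trace"):
            extract_trace(BinaryMask(np.zeros((151, 6), dtype=bool)),
                          region, duration_s=6.0, out_rate=1.0)

    def test_constant_chart_within_half_quantization_step(
            self, constant_chart, default_layout):
        chart, _ = constant_chart
        mask = binarize(chart)
        region = RegionSpec.from_layout(default_layout)[0]
        sig = extract_trace(mask, region, default_layout.seconds_per_region)
        step = 150.0 / (region.h - 1)
        assert np.abs(sig.values[sig.valid] - 140.0).max() <= step


class TestSpliceSegments:
    def _seg(self, n, start, rate=4.0):
        return TraceSignal(np.arange(n, dtype=float) + 60, rate, "fhr",
                           start_time=start)

    def test_two_ten_minute_segments_give_4800_samples(self):
        out = splice_segments(self._seg(2400, 0.0), self._seg(2400, 600.0))
        assert len(out) == 4800
        assert out.values[2400] == 60.0  # first sample of seg2

    def test_splice_with_empty_is_identity(self):
        seg = self._seg(100, 0.0)
        empty = TraceSignal(np.empty(0), 4.0, "fhr")
        out = splice_segments(seg, empty)
        assert np.array_equal(out.values, seg.values)

    def test_mismatches_rejected(self):
        with pytest.raises(ValueError, match="channel"):
            splice_segments(self._seg(10, 0.0),
                            TraceSignal(np.zeros(10), 4.0, "uc"))
        with pytest.raises(ValueError, match="rate"):
            splice_segments(self._seg(10, 0.0), self._seg(10, 0.0, rate=2.0))


class TestStandardizeToInput:
    def _pair(self, variability=8.0, seed=0):
        p = SignalParams(variability_amp=variability, seed=seed)
        return simulate_fhr(p), simulate_uc(p)

    def test_output_is_3x224x224(self):
        mi = standardize_to_input(*self._pair())
        assert mi.tensor.shape == (3, 224, 224)

    def test_zscore_mean_zero_sd_one(self):
        mi = standardize_to_input(*self._pair())
        assert abs(mi.tensor[0].mean()) < 1e-6
        assert abs(mi.tensor[0].std() - 1.0) < 1e-6

    def test_degenerate_constant_canvas_yields_zeros(self):
        # a canvas that is a single flat value has sd 0; the epsilon guard
        # must return an all-zero tensor rather than dividing by zero
        fhr = TraceSignal(np.full(4800, 135.0), 4.0, "fhr")
        uc = TraceSignal(np.full(4800, 50.0), 4.0, "uc")
        mi = standardize_to_input(fhr, uc, size=2)
        assert np.all(mi.tensor == 0.0)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="short"):
            standardize_to_input(TraceSignal(np.array([1.0]), 4.0, "fhr"),
                                 TraceSignal(np.zeros(4800), 4.0, "uc"))


class TestDigitizeChart:
    def test_output_lengths_4800_at_4hz(self, wiggly_chart):
        fhr, uc = digitize_chart(wiggly_chart[0])
        assert len(fhr) == 4800 and len(uc) == 4800

    def test_all_background_image_rejected(self, default_layout):
        blank = np.zeros((default_layout.page_size[1],
                          default_layout.page_size[0]), dtype=np.uint8)
        with pytest.raises(ValueError, match="no trace"):
            digitize_chart(blank, default_layout)

    @pytest.mark.parametrize("seed", range(4))
    def test_round_trip_rmse_within_tolerance(self, seed, default_layout):
        for chart, truth in make_dataset(1, 0.5, seed=seed,
                                         layout=default_layout):
            fhr, uc = digitize_chart(chart, default_layout)
            for rec, ref, tol in ((fhr, truth.fhr, 2.0), (uc, truth.uc, 2.0)):
                gt = ref.value_at(rec.times)
                err = rec.values[rec.valid] - gt[rec.valid]
                assert np.sqrt(np.mean(err**2)) <= tol

    def test_region_autodetection_finds_four_panels(self, wiggly_chart,
                                                    default_layout):
        chart, truth = wiggly_chart
        boxes = detect_region_boxes(binarize(chart))
        assert len(boxes) == 4
        for (bx, by, bw, bh), (lx, ly, lw, lh) in zip(
                boxes, default_layout.region_boxes):
            assert ly <= by and by + bh <= ly + lh
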