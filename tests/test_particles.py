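"""Particle quantification: background, binarization, counting, anomaly flags.

The counting/area path is cross-checked against an independent brute-force
flood-fill enumeration on small frames.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fjordcam import particles, synthetic as syn
from fjordcam.particles import (
    BackgroundModel,
    estimate_background,
    flag_anomalies,
    mean_color,
    quantify_frame,
    quantify_stack,
    sliding_median,
)
from fjordcam.video_io import FrameStack


def flood_fill_count_area(image: np.ndarray, threshold: float, min_px: int):
    """Independent oracle: 8-connected components by explicit flood fill."""
    mask = image >= threshold
    seen = np.zeros_like(mask, dtype=bool)
    h, w = mask.shape
    count, area = 0, 0
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            stack, comp = [(r0, c0)], 0
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                comp += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            if comp >= min_px:
                count += 1
                area += comp
    return count, area


def _gray_stack(frames: np.ndarray) -> FrameStack:
    from datetime import datetime, timezone

    rgb = np.repeat(frames[..., None], 3, axis=-1).astype(np.uint8)
    return FrameStack(rgb, 30.0, datetime(2025, 8, 2, tzinfo=timezone.utc))


class TestBackground:
    def test_identical_frames_give_exact_background(self):
        frame = np.full((8, 8), 37, dtype=np.uint8)
        stack = _gray_stack(np.stack([frame] * 4))
        bg = estimate_background(stack, exclude_first=False)
        assert np.array_equal(bg.image, frame.astype(float))

    def test_median_excludes_transient_pixel(self):
        frames = np.zeros((3, 8, 8), dtype=np.uint8)
        frames[1, 4, 4] = 255
        bg = estimate_background(_gray_stack(frames), exclude_first=False)
        assert bg.image[4, 4] == 0

    def test_static_line_survives_and_is_removed_from_residual(self, structured_scene):
        _, segments, truth = structured_scene
        stack = segments[0]
        bg = estimate_background(stack)
        line = truth.static_mask
        assert (bg.image[line] > 30).mean() > 0.9
        residual = np.clip(stack.frames[5][..., 0].astype(float) - bg.image, 0, None)
        # the line itself is gone; only moving particles crossing it remain
        assert (residual[line] > particles.RESIDUAL_FLOOR).mean() < 0.02
        assert np.median(residual[line]) < particles.RESIDUAL_FLOOR

    def test_overlong_window_clipped(self, small_scene, caplog):
        _, segments, _ = small_scene
        with caplog.at_level("WARNING"):
            bg = estimate_background(segments[0], window=1000)
        assert bg.window <= len(segments[0])

    def test_too_few_frames_rejected(self):
        stack = _gray_stack(np.zeros((2, 8, 8), dtype=np.uint8))
        with pytest.raises(ValueError):
            estimate_background(stack, exclude_first=False)


class TestQuantifyFrame:
    def test_frame_equal_to_background_is_empty(self):
        frame = np.full((32, 32, 3), 40, dtype=np.uint8)
        bg = BackgroundModel(np.full((32, 32), 40.0))
        s = quantify_frame(frame, bg)
        assert s.particle_count == 0 and s.area_fraction == 0.0

    def test_single_square_area_ratio(self):
        frame = np.zeros((480, 640, 3), dtype=np.uint8)
        frame[100:110, 200:210, 0] = 200
        bg = BackgroundModel(np.zeros((480, 640)))
        s = quantify_frame(frame, bg, threshold_policy="fixed", fixed_threshold=50)
        assert s.particle_count == 1
        assert s.area_fraction == pytest.approx(100 / (640 * 480))

    def test_constant_offset_cancels(self, rng):
        """A and count are invariant to adding a constant to frame and background."""
        base = (rng.random((32, 32)) * 60).astype(np.uint8)
        frame = np.repeat(base[..., None], 3, axis=-1)
        bg = BackgroundModel(np.zeros((32, 32)))
        s0 = quantify_frame(frame, bg, threshold_policy="fixed", fixed_threshold=30)
        shifted = np.clip(frame.astype(int) + 50, 0, 255).astype(np.uint8)
        bg2 = BackgroundModel(np.full((32, 32), 50.0))
        s1 = quantify_frame(shifted, bg2, threshold_policy="fixed", fixed_threshold=30)
        assert s0.particle_count == s1.particle_count
        assert s0.area_fraction == s1.area_fraction

    def test_extra_particle_increments_count(self):
        frame = np.zeros((64, 64, 3), dtype=np.uint8)
        frame[10:13, 10:13, 0] = 200
        bg = BackgroundModel(np.zeros((64, 64)))
        s0 = quantify_frame(frame, bg, threshold_policy="fixed", fixed_threshold=50)
        frame2 = frame.copy()
        frame2[40:43, 40:43, 0] = 200
        s1 = quantify_frame(frame2, bg, threshold_policy="fixed", fixed_threshold=50)
        assert s1.particle_count == s0.particle_count + 1
        assert s1.area_fraction > s0.area_fraction

    def test_saturated_frame_flagged(self):
        frame = np.full((16, 16, 3), 255, dtype=np.uint8)
        bg = BackgroundModel(np.zeros((16, 16)))
        s = quantify_frame(frame, bg)
        assert "SATURATED" in s.anomaly_flags

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_flood_fill_oracle_equivalence(self, seed):
        """count and A match exhaustive flood fill on small frames."""
        rng = np.random.default_rng(seed)
        img = (rng.random((24, 24)) < 0.15) * rng.integers(60, 200, (24, 24))
        frame = np.repeat(img[..., None], 3, axis=-1).astype(np.uint8)
        bg = BackgroundModel(np.zeros((24, 24)))
        s = quantify_frame(frame, bg, threshold_policy="fixed", fixed_threshold=50,
                           min_blob_px=2)
        count, area = flood_fill_count_area(img.astype(float), 50, 2)
        assert s.particle_count == count
        assert s.area_fraction == pytest.approx(area / img.size)

    def test_count_recovery_on_separated_scene(self, small_scene):
        """Median per-frame count error is zero for well-separated discs."""
        cfg, segments, truth = small_scene
        errs = []
        for si, stack in enumerate(segments):
            bg = estimate_background(stack, exclude_first=False)
            series = quantify_stack(stack, bg, threshold_policy="fixed",
                                    fixed_threshold=20.0)
            errs += [
                s.particle_count - truth.counts[si][s.frame_index] for s in series
            ]
        assert np.median(errs) == 0

    def test_area_recovery_within_20_percent(self, small_scene):
        cfg, segments, truth = small_scene
        stack = segments[0]
        bg = estimate_background(stack, exclude_first=False)
        series = quantify_stack(stack, bg, threshold_policy="fixed",
                                fixed_threshold=20.0)
        for s in series:
            truth_frac = truth.area_px[0][s.frame_index] / (cfg.width * cfg.height)
            assert s.area_fraction == pytest.approx(truth_frac, rel=0.2)


class TestMeanColor:
    def test_constant_frame(self):
        frame = np.empty((10, 10, 3), dtype=np.uint8)
        frame[..., 0], frame[..., 1], frame[..., 2] = 200, 10, 5
        assert mean_color(frame) == (200.0, 10.0, 5.0)

    def test_half_black_half_white(self):
        frame = np.zeros((10, 10, 3), dtype=np.uint8)
        frame[:5] = 255
        assert mean_color(frame) == (127.5, 127.5, 127.5)

    def test_seafloor_scene_is_red_dominant(self, structured_scene):
        _, segments, _ = structured_scene
        r, g, b = mean_color(segments[0].frames[1])
        assert r > 5 * g and r > 5 * b


class TestFlagAnomalies:
    @pytest.fixture(scope="class")
    def long_segment(self, structured_scene):
        cfg, _, _ = structured_scene
        tide = syn.generate_tide(2 * syn.T_M2_H * 3600 + 7200, seed=0)
        cfg2 = syn.SceneConfig(width=320, height=240, total_hours=0.2,
                               frames_per_segment=120, particle_density=20, seed=7)
        segments, _ = syn.generate_scene(cfg2, tide)
        return segments[0]

    def test_first_frame_spike_flagged_on_frame0_only(self, long_segment):
        stack, _ = syn.inject_anomalies(long_segment, [syn.FirstFrameSpike(80)])
        series = quantify_stack(stack)
        flag_anomalies(series)
        flagged = [s.frame_index for s in series if "FIRST_FRAME" in s.anomaly_flags]
        assert flagged == [0]

    def test_attachment_flagged_near_onset(self, long_segment):
        stack, log = syn.inject_anomalies(
            long_segment, [syn.LensBlob(onset=40, duration=35)]
        )
        series = quantify_stack(stack)
        flag_anomalies(series, glow_window=30)
        flagged = [s.frame_index for s in series if "ATTACHMENT" in s.anomaly_flags]
        assert flagged and abs(min(flagged) - 40) <= 5
        assert abs(max(flagged) - 74) <= 5

    def test_glow_flagged_near_onset(self, long_segment):
        stack, _ = syn.inject_anomalies(
            long_segment, [syn.SedimentGlow(onset=20, duration=80, peak=40)]
        )
        series = quantify_stack(stack)
        flag_anomalies(series, glow_window=30)
        flagged = [s.frame_index for s in series if "GLOW" in s.anomaly_flags]
        assert flagged and abs(min(flagged) - 20) <= 5

    def test_clean_scene_has_no_flags(self, long_segment):
        series = quantify_stack(long_segment)
        flag_anomalies(series, glow_window=30)
        assert sum(len(s.anomaly_flags) for s in series) == 0

    def test_short_series_checks_first_frame_only(self, long_segment):
        stack, _ = syn.inject_anomalies(long_segment, [syn.FirstFrameSpike(80)])
        from fjordcam.video_io import subsample

        series = quantify_stack(subsample(stack, 10))
        flag_anomalies(series, glow_window=30)
        assert "FIRST_FRAME" in series[0].anomaly_flags


class TestSlidingMedian:
    def test_constant_series_unchanged(self):
        x = np.full(50, 3.2)
        assert np.array_equal(sliding_median(x), x)

    def test_outlier_removed(self):
        x = np.full(50, 1.0)
        x[25] = 99.0
        sm = sliding_median(x, window_h=3.0, cadence_min=20.0)
        assert sm[25] == 1.0

    def test_kernel_length_is_nine_samples(self):
        # a window spanning fewer than 5 samples on one side leaves a
        # 4-sample-wide outlier block partly intact; 3 h / 20 min = 9 taps
        x = np.zeros(40)
        x[20:24] = 1.0
        sm = sliding_median(x, window_h=3.0, cadence_min=20.0)
        assert np.all(sm == 0.0)

    def test_degenerate_window_warns_identity(self):
        x = np.arange(5.0)
        with pytest.warns(UserWarning):
            out = sliding_median(x, window_h=0.1, cadence_min=20.0)
        assert np.array_equal(out, x)
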