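"""Generator-side properties: tide shape, scene truth, anomalies, schedule, audio."""

from __future__ import annotations

from datetime import datetime, timezone

import numpy as np
import pytest

from fjordcam import synthetic as syn
from fjordcam.tides import periodogram


class TestGenerateTide:
    def test_pure_sinusoid_peak_to_trough(self):
        t = syn.generate_tide(3 * 86400, semidiurnal_amp=1.5, spring_neap_mod=0.0)
        assert np.ptp(t.level) == pytest.approx(3.0, abs=1e-3)

    def test_zero_amplitude_is_constant(self):
        t = syn.generate_tide(3 * 86400, mean_level=2.0, semidiurnal_amp=0.0)
        assert np.allclose(t.level, 2.0)
        assert np.allclose(np.gradient(t.level), 0.0)

    def test_periodogram_peaks_at_m2(self):
        t = syn.generate_tide(6 * 86400, spring_neap_mod=0.0, sample_interval_s=600)
        est = periodogram(t.level, cadence_min=10.0)
        assert est.peak_frequency() == pytest.approx(1 / syn.T_M2_H, rel=0.05)

    def test_spring_neap_envelope_orders_cycle_ranges(self):
        t = syn.generate_tide(16 * 86400, spring_neap_mod=0.6, sample_interval_s=600)
        per = int(syn.T_M2_H * 3600 / 600)
        ranges = [
            np.ptp(t.level[k * per:(k + 1) * per])
            for k in range(t.level.size // per)
        ]
        assert min(ranges) < 0.6 * max(ranges)
        # series starts at neap: first cycle range below the global max
        assert ranges[0] < 0.9 * max(ranges)

    def test_bad_interval_rejected(self):
        with pytest.raises(ValueError, match="sample_interval"):
            syn.generate_tide(3 * 86400, sample_interval_s=0)

    def test_seed_determinism(self):
        a = syn.generate_tide(3 * 86400, noise_sigma=0.05, seed=3)
        b = syn.generate_tide(3 * 86400, noise_sigma=0.05, seed=3)
        assert np.array_equal(a.level, b.level)


class TestGenerateScene:
    def test_truth_counts_match_positions(self, small_scene):
        _, _, truth = small_scene
        truth.validate()
        for seg_counts in truth.counts:
            assert all(np.isfinite(c) for c in seg_counts)

    def test_zero_gain_means_zero_truth_flow(self, short_tide):
        cfg = syn.SceneConfig(width=160, height=120, total_hours=0.5,
                              frames_per_segment=4, particle_density=10,
                              flow_gain=0.0, seed=2)
        _, truth = syn.generate_scene(cfg, short_tide)
        flows = np.array([f for seg in truth.flow for f in seg])
        assert np.allclose(flows, 0.0)

    def test_zero_density_is_valid_empty_scene(self, short_tide):
        cfg = syn.SceneConfig(width=160, height=120, total_hours=0.5,
                              frames_per_segment=3, particle_density=0, seed=2)
        segments, truth = syn.generate_scene(cfg, short_tide)
        assert segments and all(c == 0 for seg in truth.counts for c in seg)

    def test_flow_reverses_with_tide_rate(self, short_tide):
        """Truth flow is antiparallel between rising and falling tide."""
        cfg = syn.SceneConfig(width=160, height=120, total_hours=13.0,
                              frames_per_segment=2, particle_density=5, seed=2)
        _, truth = syn.generate_scene(cfg, short_tide)
        flows = np.array([seg[0] for seg in truth.flow])
        u = flows[:, 0] ** 2 + flows[:, 1] ** 2
        moving = flows[np.sqrt(u) > 1e-3]
        angles = np.degrees(np.arctan2(moving[:, 1], moving[:, 0])) % 360
        groups = np.unique(np.round(angles))
        assert len(groups) == 2
        assert abs(abs(groups[0] - groups[1]) - 180.0) < 1e-6

    def test_mean_count_matches_density(self, short_tide):
        """Law of large numbers on the per-segment Poisson draws."""
        cfg = syn.SceneConfig(width=160, height=120, total_hours=13.0,
                              frames_per_segment=1, particle_density=85,
                              flow_gain=0.0, seed=9)
        _, truth = syn.generate_scene(cfg, short_tide)
        first = np.array([seg[0] for seg in truth.counts], dtype=float)
        tol = 3 * np.sqrt(85) / np.sqrt(first.size)
        assert abs(first.mean() - 85) < tol

    def test_seed_bit_identity(self, short_tide):
        cfg = syn.SceneConfig(width=120, height=90, total_hours=0.5,
                              frames_per_segment=3, particle_density=15, seed=4)
        s1, t1 = syn.generate_scene(cfg, short_tide)
        s2, t2 = syn.generate_scene(cfg, short_tide)
        assert np.array_equal(s1[0].frames, s2[0].frames)
        assert t1.counts == t2.counts

    def test_tide_must_span_video(self, short_tide):
        cfg = syn.SceneConfig(total_hours=1.0)
        late = datetime.fromtimestamp(
            short_tide.timestamps[-1], tz=timezone.utc
        )
        with pytest.raises(ValueError, match="span"):
            syn.generate_scene(cfg, short_tide, start_time=late)


class TestInjectAnomalies:
    def test_first_frame_spike_raises_frame0_mean(self, small_scene):
        _, segments, _ = small_scene
        out, log = syn.inject_anomalies(segments[0], [syn.FirstFrameSpike(80)])
        d0 = out.frames[0].mean() - out.frames[1].mean()
        base = segments[0].frames[0].mean() - segments[0].frames[1].mean()
        assert d0 - base == pytest.approx(80, abs=3)
        assert log[0]["type"] == "first_frame_spike" and log[0]["onset"] == 0

    def test_blob_adds_area(self, small_scene):
        _, segments, _ = small_scene
        out, log = syn.inject_anomalies(
            segments[0], [syn.LensBlob(onset=2, duration=3, area_px=5000)]
        )
        assert log[0]["area_px"] == pytest.approx(5000, rel=0.05)
        changed = (out.frames[2] != segments[0].frames[2]).any(axis=-1).sum()
        assert changed == pytest.approx(log[0]["area_px"], rel=0.1)
        assert np.array_equal(out.frames[0], segments[0].frames[0])

    def test_no_specs_is_identity(self, small_scene):
        _, segments, _ = small_scene
        out, log = syn.inject_anomalies(segments[0], [])
        assert log == []
        assert np.array_equal(out.frames, segments[0].frames)

    def test_out_of_range_rejected(self, small_scene):
        _, segments, _ = small_scene
        with pytest.raises(ValueError, match="range"):
            syn.inject_anomalies(segments[0], [syn.LensBlob(onset=5, duration=100)])


class TestGenerateSchedule:
    start = datetime(2025, 8, 1, 20, 0, tzinfo=timezone.utc)

    def test_study_duty_cycle_yields_223_segments(self):
        sched = syn.generate_schedule(self.start, total_hours=74.33, on_min=10, off_min=10)
        assert len(sched) == 223
        assert sum(d for _, d in sched) / 3600 == pytest.approx(223 * 10 / 60, rel=1e-6)

    def test_one_hour_three_segments(self):
        sched = syn.generate_schedule(self.start, 1.0, 10, 10)
        assert len(sched) == 3
        assert (sched[1][0] - sched[0][0]).total_seconds() == 1200

    def test_no_off_time_is_contiguous(self):
        sched = syn.generate_schedule(self.start, 1.0, 10, 0)
        for (s0, d0), (s1, _) in zip(sched, sched[1:]):
            assert (s1 - s0).total_seconds() == d0


class TestGenerateTestAudio:
    def test_single_tone_amplitude(self):
        x = syn.generate_test_audio(0.1, 96000, tones=[(1000.0, 0.5)])
        assert np.max(np.abs(x)) == pytest.approx(0.5, rel=1e-3)

    def test_silence(self):
        x = syn.generate_test_audio(0.1, 96000)
        assert np.all(x == 0)

    def test_two_tones_below_nyquist_ok(self):
        x = syn.generate_test_audio(0.01, 96000, tones=[(1000, 0.2), (30000, 0.2)])
        assert np.isfinite(x).all()

    def test_tone_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            syn.generate_test_audio(0.01, 96000, tones=[(48000, 0.2)])


def test_detection_table_composition():
    table = syn.generate_detection_table(datetime(2025, 8, 1, tzinfo=timezone.utc))
    assert len(table) == 478
    assert table["taxon"].value_counts()["Amphipoda"] == 225
    assert table["time_utc"].is_monotonic_increasing
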