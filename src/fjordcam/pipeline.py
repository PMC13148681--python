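"""End-to-end orchestration: simulate a deployment, analyze a bundle.

`run_simulate` writes a complete synthetic deployment bundle (scenes as PNG
frame directories, ground truth, tide, sensor log, audio, detection table,
manifest with checksums); `run_analyze` runs every measurement stage over a
bundle and writes the results (per-frame stats, per-segment flow,
correlations, periodograms, spectrogram, detection summary, report).
`simulate_and_recover_flow` is the in-memory tide-coupling recovery
experiment: render a multi-day deployment at reduced frame size, push every
segment through background removal, PIV and the dominant-flow reduction,
and correlate the recovered flow with the imposed tidal forcing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import acoustics, particles, piv, tides, video_io
from .detections import read_detection_table, summarize_detections
from .synthetic import (
    SceneConfig,
    TideSeries,
    generate_detection_table,
    generate_scene,
    generate_sensor_log,
    generate_test_audio,
    generate_tide,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "run_simulate",
    "run_analyze",
    "simulate_and_recover_flow",
]


@dataclass
class PipelineConfig:
    """Parameters of a full simulate/analyze run (YAML-serializable)."""

    output_dir: str = "fjordcam_out"
    seed: int = 0
    # simulation
    total_hours: float = 72.0
    frame_width: int = 640
    frame_height: int = 480
    fps: float = 30.0
    frames_per_segment: int = 10
    particle_density: float = 85.0
    flow_gain: float = 20.0
    flow_axis_deg: float = 90.0
    audio_seconds: float = 60.0
    audio_fs: float = 96000.0
    # analysis
    subsample_n: int = 10
    threshold_policy: str = "otsu"
    min_blob_px: int = 2
    piv_window_px: int = 64
    piv_passes: int = 1   # sparse seeding: a 32-px refinement pass is noise-prone
    tide_smooth_h: float = 2.0
    feature_smooth_h: float = 3.0
    spectrogram_fft: int = 1024
    spectrogram_resolution_s: float = 10.0
    spectrogram_band: tuple = (20.0, 43000.0)
    descent_bottom_m: float = 260.0
    descent_duration_s: float = 141.0
    descent_drop_frame: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["spectrogram_band"] = list(d["spectrogram_band"])
        Path(path).write_text(yaml.safe_dump(d))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_simulate(
    config: PipelineConfig, out_dir: Optional[str | Path] = None, force: bool = False
) -> Path:
    """Write a full synthetic deployment bundle; returns the bundle path.

    Refuses to write into an existing non-empty directory unless ``force``.
    A ``manifest.json`` lists every artifact with its SHA-256 checksum, so a
    rerun with the same config and seed is verifiably identical.
    """
    out = Path(out_dir or config.output_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    start = datetime(2025, 8, 1, 20, 0, tzinfo=timezone.utc)

    if config.total_hours <= 0:
        logger.warning("zero-duration deployment requested; writing empty bundle")
        (out / "manifest.json").write_text(json.dumps({"files": {}}))
        return out

    tide = generate_tide(
        duration_s=max(config.total_hours, 2 * 12.42) * 3600 + 3600,
        start_time_s=start.timestamp() - 1800,
        seed=config.seed,
    )
    tide.to_frame().to_csv(out / "tide.csv", index=False)
    generate_sensor_log(tide, seed=config.seed).to_csv(out / "sensor_log.csv", index=False)

    scfg = SceneConfig(
        width=config.frame_width,
        height=config.frame_height,
        fps=config.fps,
        total_hours=config.total_hours,
        frames_per_segment=config.frames_per_segment,
        particle_density=config.particle_density,
        flow_gain=config.flow_gain,
        flow_axis_deg=config.flow_axis_deg,
        seed=config.seed,
    )
    segments, truth = generate_scene(scfg, tide, start_time=start)
    scenes = out / "scenes"
    for stack in segments:
        video_io.write_segment(stack, scenes / stack.segment_id)
    pd.DataFrame(
        {
            "segment_id": [s.segment_id for s in segments],
            "start_utc": [s.start_time for s in segments],
            "n_frames": [len(s) for s in segments],
        }
    ).to_csv(out / "schedule.csv", index=False)
    truth.to_frame().to_csv(out / "truth.csv", index=False)
    (out / "anomalies.json").write_text(json.dumps(truth.anomalies))

    tones = [(f, a) for f, a in ((1000.0, 0.4), (30000.0, 0.2))
             if f < config.audio_fs / 2]
    # descent footage, stored decimated (every 10th frame -> 3 fps) so the
    # bundle stays small; the profile's resolution follows the stored rate
    descent_stack = _synthetic_descent_stack(
        config.descent_bottom_m, config.descent_duration_s, fps=3.0
    )
    video_io.write_segment(descent_stack, out / "descent")

    audio = generate_test_audio(
        config.audio_seconds, config.audio_fs,
        tones=tones, noise_sigma=0.01, seed=config.seed,
    )
    acoustics.write_wav(out / "audio.wav", audio, config.audio_fs)

    # detection count scales with recorded hours at the study-like rate of
    # roughly one detection per five minutes of footage
    video_hours = len(segments) * 10.0 / 60.0
    n_det = max(1, int(round(video_hours * 60.0 / 4.66)))
    from .synthetic import DEFAULT_TAXON_COUNTS

    taxa = list(DEFAULT_TAXON_COUNTS)
    probs = np.array(list(DEFAULT_TAXON_COUNTS.values()), dtype=float)
    draw = np.random.default_rng(config.seed).multinomial(n_det, probs / probs.sum())
    det = generate_detection_table(
        start, video_hours=video_hours,
        taxon_counts={t: int(c) for t, c in zip(taxa, draw) if c},
        seed=config.seed,
    )
    det.to_csv(out / "detections.csv", index=False)
    config.to_yaml(out / "config.yaml")

    files = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(
        json.dumps({"seed": config.seed, "files": files}, indent=1)
    )
    return out


def _synthetic_descent_stack(
    bottom_m: float, duration_s: float, fps: float = 3.0
) -> video_io.FrameStack:
    """Synthetic descent footage: G/B attenuate exponentially with depth on
    an 80-m e-folding-style scale while red is held by the camera's LEDs."""
    from .descent import descent_rate as _rate

    rate = _rate(bottom_m, duration_s)
    n = int(duration_s * fps)
    frames = np.zeros((n, 24, 32, 3), dtype=np.uint8)
    for k in range(n):
        depth = rate * k / fps
        gb = 120.0 * np.exp(-3.0 * depth / 80.0)
        frames[k, ..., 0] = 60
        frames[k, ..., 1] = int(round(gb))
        frames[k, ..., 2] = int(round(gb * 0.8))
    return video_io.FrameStack(
        frames, fps, datetime(2025, 8, 1, 19, 56, tzinfo=timezone.utc), "descent"
    )


def _segment_flow(
    stack: video_io.FrameStack, config: PipelineConfig
) -> piv.FlowVector:
    """Background-removed PIV over consecutive pairs → dominant flow."""
    bg = particles.estimate_background(stack)
    start = 1 if len(stack) > 3 else 0
    residuals = [
        np.clip(stack.frames[k][..., 0].astype(float) - bg.image, 0, None)
        for k in range(start, len(stack))
    ]
    win = min(config.piv_window_px, min(stack.shape))
    fields = []
    for a, b in zip(residuals[:-1], residuals[1:]):
        f = piv.piv_pair(a, b, window_px=win, passes=config.piv_passes)
        fields.append(piv.validate_vectors(f))
    return piv.dominant_flow(
        fields, stack.fps, segment_id=stack.segment_id, time=stack.start_time
    )


def run_analyze(
    bundle: str | Path, config: Optional[PipelineConfig] = None,
    out_dir: Optional[str | Path] = None,
) -> Path:
    """Run every measurement stage over a deployment bundle.

    A failure in one segment is logged and the segment skipped; the run
    aborts only when no segment is readable at all.
    """
    bundle = Path(bundle)
    if config is None:
        cfg_path = bundle / "config.yaml"
        config = PipelineConfig.from_yaml(cfg_path) if cfg_path.exists() else PipelineConfig()
    if isinstance(config.spectrogram_band, list):
        config.spectrogram_band = tuple(config.spectrogram_band)
    out = Path(out_dir or (bundle / "results"))
    out.mkdir(parents=True, exist_ok=True)

    seg_dirs = sorted((bundle / "scenes").glob("seg_*")) if (bundle / "scenes").exists() else []
    stats_frames, flows, seg_summaries = [], [], []
    n_failed = 0
    for seg_dir in seg_dirs:
        try:
            stack = video_io.load_segment(seg_dir)
            stack = video_io.subsample(stack, min(config.subsample_n, len(stack)))
            series = particles.quantify_stack(
                stack,
                threshold_policy=config.threshold_policy,
                min_blob_px=config.min_blob_px,
            )
            particles.flag_anomalies(series)
            stats_frames.append(particles.stats_to_frame(series, stack.segment_id))
            flow = _segment_flow(stack, config)
            flows.append(flow)
            body = series[1:] if len(series) > 1 else series  # drop switch-on frame
            seg_summaries.append(
                {
                    "segment_id": stack.segment_id,
                    "time_utc": stack.start_time,
                    "area_fraction": float(np.mean([s.area_fraction for s in body])),
                    "count": float(np.mean([s.particle_count for s in body])),
                    "mean_r": float(np.mean([s.mean_rgb[0] for s in body])),
                }
            )
        except Exception as exc:  # noqa: BLE001 - per-segment resilience
            n_failed += 1
            logger.warning("segment %s skipped: %s", seg_dir.name, exc)
    if seg_dirs and not seg_summaries:
        raise RuntimeError("no readable segments in bundle")

    results: dict = {"n_segments_analyzed": len(seg_summaries), "n_segments_failed": n_failed}

    if stats_frames:
        pd.concat(stats_frames, ignore_index=True).to_csv(out / "frame_stats.csv", index=False)
        summary = pd.DataFrame(seg_summaries)
        cadence = 20.0  # camera duty cycle: one segment every 20 min
        for col in ("area_fraction", "count", "mean_r"):
            summary[f"{col}_smooth"] = particles.sliding_median(
                summary[col].to_numpy(), config.feature_smooth_h, cadence
            )
        summary.to_csv(out / "segment_summary.csv", index=False)
        pd.DataFrame(
            {
                "segment_id": [f.segment_id for f in flows],
                "time_utc": [f.time for f in flows],
                "speed_px_s": [f.speed_px_s for f in flows],
                "direction_deg": [f.direction_deg for f in flows],
                "n_vectors_used": [f.n_vectors_used for f in flows],
                "missing": [f.missing for f in flows],
            }
        ).to_csv(out / "flow.csv", index=False)

        # periodograms of the per-segment feature series
        psd_rows = []
        for col in ("area_fraction", "count", "mean_r"):
            if len(summary) >= 4:
                est = tides.periodogram(summary[col].to_numpy(), cadence)
                psd_rows.append(
                    pd.DataFrame(
                        {
                            "variable": col,
                            "frequency_per_h": est.frequencies,
                            "power": est.power,
                            "lo95": est.lo95,
                            "hi95": est.hi95,
                        }
                    )
                )
        if psd_rows:
            pd.concat(psd_rows, ignore_index=True).to_csv(out / "psd.csv", index=False)

        # tide coupling
        tide_path = bundle / "tide.csv"
        if tide_path.exists():
            tide = TideSeries.from_frame(pd.read_csv(tide_path))
            rate = tides.sea_level_rate(tide, config.tide_smooth_h)
            try:
                kept, rate_at = tides.align_series(flows, tide, rate)
                dirs = np.array([f.direction_deg for f in kept])
                speeds = np.array([f.speed_px_s for f in kept])
                axis = tides.estimate_flow_axis(dirs)
                signed = tides.signed_speed(speeds, dirs, axis)
                corr = {}
                if len(kept) >= 3:
                    c1 = tides.pearson(rate_at, signed, "rate_vs_signed_flow")
                    c2 = tides.pearson(np.abs(rate_at), speeds, "abs_rate_vs_speed")
                    for c in (c1, c2):
                        corr[c.variables] = {"r": c.r, "p": c.p_value, "n": c.n}
                corr["flow_axis_deg"] = axis
                (out / "correlation.json").write_text(json.dumps(corr, indent=1))
                results["correlation"] = corr
            except ValueError as exc:
                logger.warning("tide coupling skipped: %s", exc)

    # descent light profile
    descent_dir = bundle / "descent"
    if descent_dir.exists():
        from .descent import descent_rate, frames_to_depth, rgb_depth_profile

        stack = video_io.load_segment(descent_dir)
        rate = descent_rate(config.descent_bottom_m, config.descent_duration_s)
        depths = frames_to_depth(
            stack, config.descent_drop_frame, rate, config.descent_bottom_m
        )
        prof = rgb_depth_profile(stack, depths, bin_m=1.0, rate_m_s=rate)
        prof.to_frame().to_csv(out / "descent_profile.csv", index=False)
        results["descent_rate_m_s"] = round(rate, 3)
        results["gb_transition_depth_m"] = prof.gb_transition_depth_m

    # acoustics
    wav_path = bundle / "audio.wav"
    if wav_path.exists():
        audio, fs = acoustics.read_wav(wav_path)
        spec = acoustics.long_term_spectrogram(
            audio, fs, config.spectrogram_fft,
            config.spectrogram_resolution_s, tuple(config.spectrogram_band),
        )
        spec.save(out / "spectrogram.csv")
        results["spectrogram_peak_hz"] = spec.peak_frequency()

    # detections
    det_path = bundle / "detections.csv"
    if det_path.exists():
        det = read_detection_table(det_path)
        video_hours = len(seg_dirs) * 10.0 / 60.0 if seg_dirs else config.total_hours / 2
        summary_det = summarize_detections(det, video_hours)
        summary_det.to_csv(out / "detection_summary.csv", index=False)
        results["detections_total"] = summary_det.attrs["total"]
        results["mean_detection_interval_min"] = summary_det.attrs["mean_interval_min"]

    (out / "results.json").write_text(json.dumps(results, indent=1, default=str))
    _write_report(out, results)
    return out


def _write_report(out: Path, results: dict) -> None:
    lines = ["# fjordcam analysis report", ""]
    for k, v in results.items():
        lines.append(f"- **{k}**: {v}")
    (out / "report.md").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Tide-coupling recovery experiment
# ---------------------------------------------------------------------------

def simulate_and_recover_flow(
    seed: int = 0,
    days: float = 3.0,
    frame_size: tuple = (128, 96),
    frames_per_segment: int = 3,
    particle_density: float = 40.0,
    flow_gain: float = 20.0,
    flow_axis_deg: float = 90.0,
    piv_window: int = 32,
    rate_threshold: float = 0.02,
) -> dict:
    """Full-pipeline recovery of tidal flow modulation on a synthetic deployment.

    Renders a ``days``-long deployment at 20-min segment cadence and reduced
    frame size, runs background removal + single-pass PIV + dominant-flow
    reduction on every segment, and correlates the recovered flow with the
    imposed (smoothed) sea-level rate. Uses the generator's configured flow
    axis for the signed projection, since it is ground truth here.

    Returns a dict with the two correlation results, the circular mean
    directions of rising- and falling-tide segments and their separation,
    and the recovered flow series.
    """
    w, h = frame_size
    start = datetime(2025, 8, 1, 20, 0, tzinfo=timezone.utc)
    tide = generate_tide(
        duration_s=days * 86400 + 3600,
        start_time_s=start.timestamp() - 1800,
        sample_interval_s=120.0,
        seed=seed,
    )
    cfg = SceneConfig(
        width=w, height=h, fps=30.0,
        total_hours=days * 24.0,
        frames_per_segment=frames_per_segment,
        particle_density=particle_density,
        flow_gain=flow_gain,
        flow_axis_deg=flow_axis_deg,
        background_elements=(),
        seed=seed,
    )
    segments, truth = generate_scene(cfg, tide, start_time=start)

    flows = []
    for stack in segments:
        bg = particles.estimate_background(stack, exclude_first=False)
        residuals = [
            np.clip(stack.frames[k][..., 0].astype(float) - bg.image, 0, None)
            for k in range(len(stack))
        ]
        fields = [
            piv.validate_vectors(piv.piv_pair(a, b, window_px=piv_window, passes=1))
            for a, b in zip(residuals[:-1], residuals[1:])
        ]
        flows.append(
            piv.dominant_flow(fields, stack.fps, stack.segment_id, stack.start_time)
        )

    rate = tides.sea_level_rate(tide, smooth_window_h=2.0)
    kept, rate_at = tides.align_series(flows, tide, rate)
    dirs = np.array([f.direction_deg for f in kept])
    speeds = np.array([f.speed_px_s for f in kept])
    signed = tides.signed_speed(speeds, dirs, flow_axis_deg)

    corr_signed = tides.pearson(rate_at, signed, "rate_vs_signed_flow")
    corr_speed = tides.pearson(np.abs(rate_at), speeds, "abs_rate_vs_speed")

    rising = dirs[rate_at > rate_threshold]
    falling = dirs[rate_at < -rate_threshold]
    dir_rising = piv.circular_mean_deg(rising) if rising.size else float("nan")
    dir_falling = piv.circular_mean_deg(falling) if falling.size else float("nan")
    sep = abs(tides.signed_angle(dir_rising - dir_falling, 0.0))

    return {
        "corr_signed": corr_signed,
        "corr_speed": corr_speed,
        "direction_rising_deg": dir_rising,
        "direction_falling_deg": dir_falling,
        "direction_separation_deg": float(sep),
        "flows": kept,
        "rate_at_flows": rate_at,
        "truth": truth,
        "n_missing": sum(1 for f in flows if f.missing),
    }
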