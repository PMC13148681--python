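"""Frame-stack I/O.

The canonical interchange format is a directory of losslessly compressed
PNG frames (``frame_000000.png`` …) with a JSON sidecar carrying the frame
rate, UTC start time and segment id; this keeps round-trips bit-identical
and avoids codec nondeterminism. Standard containers (MOV/MP4/AVI) are
read through :mod:`imageio` when a decoding backend is available.

All times are UTC. When a directory carries no sidecar, a trailing
``_YYYYMMDDThhmmssZ`` token in its name is accepted as the start time;
missing metadata is an error, never guessed.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["FrameStack", "load_segment", "write_segment", "subsample"]

SIDECAR_NAME = "segment.json"
_FRAME_PATTERN = "frame_{:06d}.png"
_TS_RE = re.compile(r"_(\d{8}T\d{6})Z$")


@dataclass
class FrameStack:
    """Ordered RGB frames of one recording segment.

    frames : uint8 array (n, height, width, 3); fps > 0; start_time is the
    UTC time of frame 0; segment_id identifies the source file.
    """

    frames: np.ndarray
    fps: float
    start_time: datetime
    segment_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("frames must have shape (n, h, w, 3)")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.start_time.tzinfo is None:
            self.start_time = self.start_time.replace(tzinfo=timezone.utc)

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape[1:3]

    @property
    def duration_s(self) -> float:
        return len(self) / self.fps

    def frame_time(self, k: int) -> datetime:
        """UTC timestamp of frame ``k`` (start_time + k/fps)."""
        from datetime import timedelta

        return self.start_time + timedelta(seconds=k / self.fps)


def write_segment(stack: FrameStack, path: str | Path) -> Path:
    """Write a stack as a PNG frame directory with a JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for k in range(len(stack)):
        iio.imwrite(path / _FRAME_PATTERN.format(k), stack.frames[k])
    sidecar = {
        "fps": stack.fps,
        "start_time": stack.start_time.strftime("%Y-%m-%dT%H:%M:%S.%f%z"),
        "segment_id": stack.segment_id,
        "n_frames": len(stack),
    }
    (path / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=1))
    return path


def _parse_sidecar_time(s: str) -> datetime:
    return datetime.strptime(s, "%Y-%m-%dT%H:%M:%S.%f%z")


def _load_directory(path: Path, fps_override: float | None) -> FrameStack:
    frame_files = sorted(path.glob("frame_*.png")) + sorted(path.glob("frame_*.tif*"))
    if not frame_files:
        raise ValueError(f"no frames found in {path}")
    sidecar_path = path / SIDECAR_NAME
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        fps = float(meta["fps"])
        start = _parse_sidecar_time(meta["start_time"])
        segment_id = meta.get("segment_id", path.name)
    else:
        m = _TS_RE.search(path.name)
        if m is None:
            raise ValueError(
                f"{path}: no sidecar and no _YYYYMMDDThhmmssZ timestamp in name; "
                "start time cannot be guessed"
            )
        start = datetime.strptime(m.group(1), "%Y%m%dT%H%M%S").replace(
            tzinfo=timezone.utc
        )
        if fps_override is None:
            raise ValueError(f"{path}: no sidecar; fps_override is required")
        fps, segment_id = fps_override, path.name
    if fps_override is not None:
        fps = fps_override

    frames = []
    shape = None
    for k, f in enumerate(frame_files):
        try:
            img = iio.imread(f)
        except Exception as exc:  # noqa: BLE001 - report the failing frame
            raise ValueError(f"unreadable frame index {k} ({f.name}): {exc}") from exc
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValueError(
                f"inconsistent frame shapes: frame {k} is {img.shape}, expected {shape}"
            )
        frames.append(img[..., :3])
    return FrameStack(np.stack(frames), fps, start, segment_id)


def _load_container(path: Path, fps_override: float | None) -> FrameStack:
    try:
        import imageio

        reader = imageio.get_reader(str(path))
    except Exception as exc:  # no decoding backend for this container
        raise ValueError(
            f"cannot decode container {path}: no imageio backend available ({exc}); "
            "convert to a PNG frame directory"
        ) from exc
    meta = reader.get_meta_data()
    fps = fps_override or meta.get("fps")
    if not fps:
        raise ValueError(f"{path}: container carries no fps; pass fps_override")
    m = _TS_RE.search(path.stem)
    if m is None:
        raise ValueError(
            f"{path}: container name carries no _YYYYMMDDThhmmssZ timestamp; "
            "start time cannot be guessed"
        )
    start = datetime.strptime(m.group(1), "%Y%m%dT%H%M%S").replace(tzinfo=timezone.utc)
    frames = np.stack([np.asarray(f)[..., :3] for f in reader])
    reader.close()
    return FrameStack(frames, float(fps), start, path.stem)


def load_segment(path: str | Path, fps_override: float | None = None) -> FrameStack:
    """Load one recording segment from a frame directory or container.

    Directories require either the JSON sidecar or a filename timestamp plus
    ``fps_override``; containers require a decodable format and a filename
    timestamp. Unreadable frames and inconsistent shapes raise with the
    offending frame index.
    """
    path = Path(path)
    if path.is_dir():
        return _load_directory(path, fps_override)
    if path.is_file():
        return _load_container(path, fps_override)
    raise FileNotFoundError(path)


def subsample(stack: FrameStack, n: int, from_start: bool = True) -> FrameStack:
    """First ``n`` consecutive frames (metadata preserved).

    The study analyzed the first 10 frames of each 10-min file (0.33 s at
    30 fps); this is the operation that selects them.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(stack):
        raise ValueError(f"n={n} exceeds stack length {len(stack)}")
    if from_start:
        frames = stack.frames[:n]
        start = stack.start_time
    else:
        frames = stack.frames[len(stack) - n:]
        start = stack.frame_time(len(stack) - n)
    return dataclasses.replace(stack, frames=frames.copy(), start_time=start)
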