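"""Multi-channel time-lapse image stacks and their on-disk layout.

A stack is written as one multi-page TIFF per channel plus a JSON
sidecar (`stack.json`) holding channel names, time stamps (min) and the
pixel size (μm/px), so any conforming stack can be re-read without
guessing metadata from file names.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

SIDECAR_NAME = "stack.json"


@dataclass
class ImageStack:
    """Ordered frames for one or more channels.

    frames[channel] has shape (n_frames, height, width); all channels
    share the same frame times and geometry.
    """

    frames: dict[str, np.ndarray]
    times: np.ndarray  # min, strictly increasing
    pixel_size: float  # μm/px
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time stamps must be strictly increasing")
        shapes = {ch: a.shape for ch, a in self.frames.items()}
        first = next(iter(shapes.values()))
        if any(s != first for s in shapes.values()):
            raise ValueError(f"channel shapes differ: {shapes}")
        if first[0] != self.times.size:
            raise ValueError("number of frames does not match time stamps")

    @property
    def channels(self) -> list[str]:
        return list(self.frames)

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    def frame(self, channel: str, index: int) -> np.ndarray:
        return self.frames[channel][index]

    def select_frames(self, indices) -> "ImageStack":
        idx = np.asarray(indices, dtype=int)
        return ImageStack(
            frames={ch: a[idx] for ch, a in self.frames.items()},
            times=self.times[idx],
            pixel_size=self.pixel_size,
            meta=dict(self.meta),
        )


def write_stack(stack: ImageStack, out_dir: str | Path) -> Path:
    """Write one TIFF per channel plus the JSON sidecar; returns out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ch, arr in stack.frames.items():
        tifffile.imwrite(out / f"{ch}.tif", arr, photometric="minisblack")
    sidecar = {
        "channels": stack.channels,
        "times_min": stack.times.tolist(),
        "pixel_size_um": stack.pixel_size,
        "meta": _jsonable(stack.meta),
    }
    (out / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=2))
    return out


def read_stack(in_dir: str | Path) -> ImageStack:
    """Read a stack written by :func:`write_stack`."""
    src = Path(in_dir)
    sidecar = json.loads((src / SIDECAR_NAME).read_text())
    frames = {}
    for ch in sidecar["channels"]:
        arr = tifffile.imread(src / f"{ch}.tif")
        if arr.ndim == 2:  # single-frame stacks come back squeezed
            arr = arr[None]
        frames[ch] = arr
    return ImageStack(
        frames=frames,
        times=np.asarray(sidecar["times_min"], dtype=float),
        pixel_size=float(sidecar["pixel_size_um"]),
        meta=sidecar.get("meta", {}),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
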