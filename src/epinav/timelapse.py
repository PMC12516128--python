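"""Calibrated multi-channel time-lapse container and TIFF round-trip.

Pixel data are indexed ``(frame, channel, row, col)``.  Row 0 is the top of
the field of view and pixel centers sit at integer (row, col) coordinates,
so a physical position in micrometres maps to pixels as
``col = x_um / pixel_size_um``, ``row = y_um / pixel_size_um``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["TimeLapse"]


@dataclass
class TimeLapse:
    pixels: np.ndarray  # (T, C, H, W), non-negative
    channel_names: tuple[str, ...]
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ValueError("pixels must be (frame, channel, row, col)")
        if len(self.channel_names) != self.pixels.shape[1]:
            raise ValueError("channel_names must match the channel axis")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("calibration fields must be strictly positive")
        if self.pixels.size and float(self.pixels.min()) < 0:
            raise ValueError("intensities must be non-negative")

    # ------------------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape_px(self) -> tuple[int, int]:
        return self.pixels.shape[2], self.pixels.shape[3]

    def channel(self, name: str) -> np.ndarray:
        """(T, H, W) view of one named channel."""
        try:
            i = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel {name!r}; have {self.channel_names}") from None
        return self.pixels[:, i]

    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames, dtype=float) * self.frame_interval_s

    # ------------------------------------------------------------------
    def write_tiff(self, path: str | Path) -> None:
        """Write a frame-major, channel-interleaved multi-page TIFF.

        Calibration and channel names go into the ImageJ-style metadata
        plus a JSON description, so :meth:`read_tiff` recovers them.
        """
        meta = {
            "channel_names": list(self.channel_names),
            "pixel_size_um": self.pixel_size_um,
            "frame_interval_s": self.frame_interval_s,
        }
        tifffile.imwrite(
            str(path),
            self.pixels.astype(np.float32),
            photometric="minisblack",
            planarconfig="separate",
            metadata={"axes": "TCYX"},
            description=json.dumps(meta),
            resolution=(1.0 / self.pixel_size_um, 1.0 / self.pixel_size_um),
        )

    @classmethod
    def read_tiff(cls, path: str | Path) -> "TimeLapse":
        with tifffile.TiffFile(str(path)) as tf:
            arr = tf.asarray()
            desc = tf.pages[0].description or "{}"
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
        if arr.ndim == 3:  # single channel stored (T, H, W)
            arr = arr[:, None]
        names = tuple(meta.get("channel_names", [f"ch{i}" for i in range(arr.shape[1])]))
        return cls(
            pixels=arr,
            channel_names=names,
            pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
            frame_interval_s=float(meta.get("frame_interval_s", 1.0)),
        )
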