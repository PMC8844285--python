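"""In-memory containers for TIRF time-lapse data.

``ImageStack`` is the common currency of every imaging operation: an ordered
sequence of same-shaped 2-D intensity frames with per-frame timestamps and
pixel-size metadata.  ``RegionSpec`` carries the analysis ROI and the
gain-reference background rectangle (half-open, 0-based, row-major).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

__all__ = ["ImageStack", "RegionSpec", "MetricSeries", "Rect"]

# (row_start, row_stop, col_start, col_stop), half-open
Rect = tuple[int, int, int, int]


def _check_rect(rect: Rect, shape: tuple[int, int], name: str) -> None:
    r0, r1, c0, c1 = rect
    if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
        raise InvalidInputError(
            f"{name} rectangle {rect} is empty or outside frame bounds {shape}"
        )


@dataclass(frozen=True)
class RegionSpec:
    """Analysis ROI plus a disjoint background rectangle.

    The background region must cover an area where filaments remain
    unaffected by the field (by convention the upper-right corner of the
    frame); its per-frame mean intensity is the camera-gain reference.
    """

    roi: Rect
    background: Rect

    def validate(self, shape: tuple[int, int]) -> None:
        _check_rect(self.roi, shape, "roi")
        _check_rect(self.background, shape, "background")
        r0, r1, c0, c1 = self.roi
        b0, b1, d0, d1 = self.background
        if max(r0, b0) < min(r1, b1) and max(c0, d0) < min(d1, c1):
            raise InvalidInputError("roi and background rectangles overlap")

    def roi_slice(self) -> tuple[slice, slice]:
        r0, r1, c0, c1 = self.roi
        return slice(r0, r1), slice(c0, c1)

    def background_slice(self) -> tuple[slice, slice]:
        r0, r1, c0, c1 = self.background
        return slice(r0, r1), slice(c0, c1)

    @property
    def roi_size(self) -> int:
        r0, r1, c0, c1 = self.roi
        return (r1 - r0) * (c1 - c0)

    @classmethod
    def default_for_shape(cls, shape: tuple[int, int], corner_frac: float = 0.15) -> "RegionSpec":
        """Background = upper-right ``corner_frac`` x ``corner_frac`` corner;
        ROI = everything below the top strip."""
        h, w = shape
        rb = max(1, int(round(corner_frac * h)))
        cb = max(1, int(round(corner_frac * w)))
        return cls(roi=(rb, h, 0, w), background=(0, rb, w - cb, w))


@dataclass
class ImageStack:
    """Ordered stack of 2-D intensity frames with timestamps.

    Frames are stored as a single float64 array of shape (n, h, w); raw
    integer data is promoted on construction so later subtractions cannot
    wrap around.
    """

    frames: np.ndarray
    times: np.ndarray
    frame_rate: float
    pixel_size_um: float = 0.217

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise InvalidInputError("stack needs >= 1 frame of identical shape (n, h, w)")
        if self.times.shape != (self.frames.shape[0],):
            raise InvalidInputError("one timestamp per frame required")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("frame times must be strictly increasing")
        if self.frame_rate <= 0 or self.pixel_size_um <= 0:
            raise InvalidInputError("frame rate and pixel size must be > 0")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @classmethod
    def from_frames(
        cls,
        frames,
        frame_rate: float = 2.47,
        pixel_size_um: float = 0.217,
        times=None,
    ) -> "ImageStack":
        frames = np.asarray(frames, dtype=float)
        if times is None:
            times = np.arange(frames.shape[0]) / frame_rate
        return cls(frames=frames, times=np.asarray(times, float),
                   frame_rate=frame_rate, pixel_size_um=pixel_size_um)

    def with_frames(self, frames: np.ndarray) -> "ImageStack":
        return replace(self, frames=np.asarray(frames, dtype=float))

    def nearest_index(self, t: float) -> int:
        """Index of the frame whose timestamp is nearest to ``t``."""
        return int(np.argmin(np.abs(self.times - t)))


@dataclass
class MetricSeries:
    """A labelled scalar time series (e.g. the MDI-speed trace)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise InvalidInputError("times and values must have equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("series times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "value": self.values,
                             "units": self.units, "label": self.label})
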