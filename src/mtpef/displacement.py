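"""Microtubule displacement index (MDI) and its speed.

The MDI between two frames is the mean absolute per-pixel intensity
difference over the region of interest,

    MDI = (1/|ROI|) * sum_{[i,j] in ROI} |I_ij(t2) - I_ij(t1)|,

which registers every pixel where fluorescent mass appeared or disappeared
without requiring segmentation or tracking of individual filaments.
Evaluated between the frames before and after a pulse train it measures the
overall displacement caused by that train; evaluated frame-to-frame and
rescaled by the frame interval it becomes the MDI *speed* (units 1/s), a
time-resolved displacement trace.

Camera auto-gain drifts multiply every pixel by an unknown per-frame factor,
which would contaminate the difference metric.  ``correct_gain`` removes it
by dividing each frame by the mean intensity of a background region where
filaments stay put, making the metric exactly invariant to per-frame scalar
gains in the noise-free limit.
"""

from __future__ import annotations

import numpy as np

from .exceptions import DegenerateBackgroundError, InvalidInputError
from .stack import ImageStack, MetricSeries, Rect, RegionSpec

__all__ = [
    "correct_gain",
    "mdi",
    "mdi_endpoint",
    "mdi_speed_series",
    "estimate_threshold_voltage",
]


def correct_gain(stack: ImageStack, regions: RegionSpec) -> ImageStack:
    """Divide every frame by its own background-region mean.

    After correction the background mean is exactly 1 in every frame, so any
    positive per-frame multiplicative gain applied to the raw data cancels.
    """
    regions.validate(stack.shape)
    bg = stack.frames[(slice(None),) + regions.background_slice()]
    means = bg.mean(axis=(1, 2))
    if np.any(means <= 0):
        bad = int(np.argmax(means <= 0))
        raise DegenerateBackgroundError(
            f"background mean is non-positive in frame {bad}"
        )
    return stack.with_frames(stack.frames / means[:, None, None])


def mdi(frame_t1: np.ndarray, frame_t2: np.ndarray, roi: Rect) -> float:
    """Mean absolute per-pixel intensity difference over the ROI."""
    a = np.asarray(frame_t1, dtype=float)
    b = np.asarray(frame_t2, dtype=float)
    if a.shape != b.shape:
        raise InvalidInputError(f"frame shapes differ: {a.shape} vs {b.shape}")
    _check_roi(roi, a.shape)
    r0, r1, c0, c1 = roi
    return float(np.mean(np.abs(b[r0:r1, c0:c1] - a[r0:r1, c0:c1])))


def mdi_endpoint(
    stack: ImageStack,
    regions: RegionSpec,
    t_pre: float,
    t_post: float,
    gain_correct: bool = True,
) -> float:
    """MDI between the frames nearest ``t_pre`` and ``t_post`` (gain-corrected).

    With t_pre before and t_post after a pulse train this is the overall
    displacement caused by that train.
    """
    if not (t_pre < t_post):
        raise InvalidInputError("t_pre must be earlier than t_post")
    if t_pre < stack.times[0] or t_post > stack.times[-1]:
        raise InvalidInputError("requested times fall outside the recording")
    work = correct_gain(stack, regions) if gain_correct else stack
    i = work.nearest_index(t_pre)
    j = work.nearest_index(t_post)
    return mdi(work.frames[i], work.frames[j], regions.roi)


def mdi_speed_series(
    stack: ImageStack, regions: RegionSpec, gain_correct: bool = True
) -> MetricSeries:
    """Frame-to-frame MDI rescaled to the second time scale (units 1/s).

    Each successive frame pair contributes one sample: MDI divided by the
    pair's time interval (equivalently multiplied by the local frame rate),
    timestamped at the pair midpoint.  Length is n_frames - 1.
    """
    if len(stack) < 2:
        raise InvalidInputError("MDI speed needs at least two frames")
    work = correct_gain(stack, regions) if gain_correct else stack
    r0, r1, c0, c1 = regions.roi
    _check_roi(regions.roi, work.shape)
    roi_frames = work.frames[:, r0:r1, c0:c1]
    diffs = np.mean(np.abs(np.diff(roi_frames, axis=0)), axis=(1, 2))
    dt = np.diff(work.times)
    mid = 0.5 * (work.times[:-1] + work.times[1:])
    return MetricSeries(times=mid, values=diffs / dt,
                        label="MDI speed", units="1/s")


def estimate_threshold_voltage(
    voltages,
    peak_speeds,
    noise_floor: float,
    k: float = 3.0,
):
    """Smallest voltage whose peak MDI speed exceeds ``k`` times the noise floor.

    ``noise_floor`` is the median pre-pulse MDI speed of the recording.
    Returns ``None`` when no voltage qualifies.
    """
    v = np.asarray(voltages, dtype=float)
    p = np.asarray(peak_speeds, dtype=float)
    if v.size == 0 or v.shape != p.shape:
        raise InvalidInputError("need equal-length, non-empty voltage and peak series")
    if np.any(np.diff(v) <= 0):
        raise InvalidInputError("voltages must be strictly increasing")
    if k <= 1:
        raise InvalidInputError("multiplier k must exceed 1")
    hits = np.nonzero(p > k * noise_floor)[0]
    return float(v[hits[0]]) if hits.size else None


def _check_roi(roi: Rect, shape: tuple[int, int]) -> None:
    r0, r1, c0, c1 = roi
    if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
        raise InvalidInputError(f"roi {roi} empty or outside frame bounds {shape}")
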