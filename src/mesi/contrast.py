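"""Speckle-contrast computation from raw intensity frames.

Contrast is K = sigma / I over a small sliding window (5x5 or 7x7); the
squared contrast K² is the canonical stored quantity because every model
equation downstream consumes K².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .models import ExposureSet

__all__ = ["RawFrameStack", "ContrastStack", "compute_contrast", "average_contrast"]


@dataclass
class RawFrameStack:
    """Raw intensity frames, one (or ``replicates``) per exposure time."""

    frames: np.ndarray  # (n_frames, H, W)
    exposure_set: ExposureSet
    replicates: int = 1

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, H, W) array")
        n = self.frames.shape[0]
        if n % self.replicates:
            raise ValueError("frame count not divisible by replicate count")
        if n // self.replicates != len(self.exposure_set):
            raise ValueError(
                "frame count does not match exposure count x replicates"
            )


@dataclass
class ContrastStack:
    """Squared speckle contrast indexed by (exposure, row, col).

    ``valid`` marks pixels whose windows were entirely inside the frame and
    had non-zero mean; border pixels computed with reflective padding are
    flagged invalid but still carry values.
    """

    k2: np.ndarray  # (n_exposures, H, W)
    exposure_set: ExposureSet
    valid: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.k2 = np.atleast_3d(np.asarray(self.k2, dtype=float))
        if self.k2.shape[0] != len(self.exposure_set):
            raise ValueError("exposure axis does not match exposure set")
        finite = np.isfinite(self.k2)
        if np.any(self.k2[finite] < 0):
            raise ValueError("squared contrast must be non-negative")
        if self.valid is None:
            self.valid = np.ones(self.k2.shape[1:], dtype=bool)

    @property
    def shape(self):
        return self.k2.shape


def _window_contrast(frame: np.ndarray, window: int) -> np.ndarray:
    """K² of one frame: sample std / mean over a sliding window, squared."""
    img = frame.astype(float)
    n = window * window
    mean = ndimage.uniform_filter(img, window, mode="reflect")
    meansq = ndimage.uniform_filter(img * img, window, mode="reflect")
    # sample (N-1) variance; tiny negatives from roundoff are clipped
    var = np.maximum(meansq - mean * mean, 0.0) * (n / (n - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        k2 = var / (mean * mean)
    return np.where(mean > 0, k2, np.nan)


def compute_contrast(raw: RawFrameStack, window: int = 7) -> ContrastStack:
    """Convert raw frames to a squared-contrast stack.

    Replicate frames at the same exposure are converted individually and
    their contrast maps averaged (contrast averaging, not intensity
    averaging, preserves the speckle statistics).
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    n_exp = len(raw.exposure_set)
    h, w = raw.frames.shape[1:]
    k2 = np.empty((n_exp, h, w))
    for i in range(n_exp):
        group = raw.frames[i * raw.replicates : (i + 1) * raw.replicates]
        k2[i] = np.mean([_window_contrast(f, window) for f in group], axis=0)
    half = window // 2
    valid = np.zeros((h, w), dtype=bool)
    valid[half : h - half, half : w - half] = True
    valid &= np.all(np.isfinite(k2), axis=0)
    return ContrastStack(k2, raw.exposure_set, valid)


def average_contrast(
    stacks: Sequence[ContrastStack], window_len: int | None = None
) -> ContrastStack:
    """Elementwise temporal mean over (the trailing ``window_len``) stacks."""
    if not stacks:
        raise ValueError("need at least one stack")
    if window_len is not None:
        stacks = stacks[-window_len:]
    ref = stacks[0]
    for s in stacks[1:]:
        if s.k2.shape != ref.k2.shape or not np.allclose(
            s.exposure_set.times, ref.exposure_set.times
        ):
            raise ValueError("stacks must share geometry and exposures")
    k2 = np.mean([s.k2 for s in stacks], axis=0)
    valid = np.logical_and.reduce([s.valid for s in stacks])
    return ContrastStack(k2, ref.exposure_set, valid)
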