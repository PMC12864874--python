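"""ROI cropping, flat-field correction and corrupted-frame screening.

Flat-field correction is the standard two-point detector calibration

    T = (I - D) / (B - D)

with ``D`` the dark (offset) frame and ``B`` the bright (gain/illumination)
frame, mapping the bright level to 1. Pixels where the denominator is at or
below ``eps`` — dead detector regions — are flagged invalid rather than set
to NaN, so Fourier transforms downstream stay finite. Saturated pixels in
the bright or corrected frame are likewise flagged: a clipped pixel fakes
visibility loss and would bleed into the dark-field channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .datamodel import Frame, FrameStack

__all__ = [
    "ROI",
    "CorrectedFrame",
    "crop",
    "flat_field",
    "screen_corrupted",
]

MIN_ROI_DIM = 16
SATURATION_16BIT = float(np.iinfo(np.uint16).max)


@dataclass(frozen=True)
class ROI:
    """Half-open rectangular window [row0, row0+height) x [col0, col0+width)."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("ROI origin must be non-negative")
        if self.height < MIN_ROI_DIM or self.width < MIN_ROI_DIM:
            raise ValueError(f"ROI sides must be >= {MIN_ROI_DIM} pixels")

    def validate_within(self, shape: tuple[int, int]) -> None:
        if self.row0 + self.height > shape[0]:
            raise ValueError(
                f"ROI bottom edge {self.row0 + self.height} exceeds frame height {shape[0]}"
            )
        if self.col0 + self.width > shape[1]:
            raise ValueError(
                f"ROI right edge {self.col0 + self.width} exceeds frame width {shape[1]}"
            )

    @property
    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row0, self.row0 + self.height),
            slice(self.col0, self.col0 + self.width),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "roi": {
                        "row0": self.row0,
                        "col0": self.col0,
                        "height": self.height,
                        "width": self.width,
                    }
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "ROI":
        with open(path) as fh:
            d = yaml.safe_load(fh)["roi"]
        return cls(d["row0"], d["col0"], d["height"], d["width"])


@dataclass
class CorrectedFrame:
    """Flat-field-normalized transmission image with a validity mask."""

    pixels: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.pixels.shape != self.valid.shape:
            raise ValueError("pixels and validity mask must share a shape")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("corrected frame contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def crop(frame: Frame, roi: ROI) -> Frame:
    """Crop a frame to the ROI; values are bit-equal to the source window."""
    roi.validate_within(frame.shape)
    return frame.with_pixels(frame.pixels[roi.slices].copy())


def crop_corrected(cf: CorrectedFrame, roi: ROI) -> CorrectedFrame:
    roi.validate_within(cf.shape)
    return CorrectedFrame(cf.pixels[roi.slices].copy(), cf.valid[roi.slices].copy())


def flat_field(
    frame: Frame,
    dark: Frame,
    bright: Frame,
    eps: float | None = None,
    saturation: float | None = SATURATION_16BIT,
) -> CorrectedFrame:
    """Dark-subtract and bright-normalize a frame.

    Parameters
    ----------
    eps
        Denominator guard; defaults to ``1e-6 * max(bright)``, which makes the
        correction invariant under a global detector-gain rescaling.
    saturation
        ADU ceiling; pixels at or above it in the bright or input frame are
        flagged invalid. Pass ``None`` to disable.
    """
    if not (frame.shape == dark.shape == bright.shape):
        raise ValueError(
            f"shape mismatch: frame {frame.shape}, dark {dark.shape}, bright {bright.shape}"
        )
    if eps is None:
        eps = 1e-6 * float(np.max(bright.pixels))
    if eps <= 0:
        raise ValueError("eps must be positive")
    denom = bright.pixels - dark.pixels
    valid = denom > eps
    if saturation is not None:
        valid &= bright.pixels < saturation
        valid &= frame.pixels < saturation
    out = np.zeros_like(frame.pixels)
    np.divide(frame.pixels - dark.pixels, denom, out=out, where=valid)
    out[~valid] = 0.0
    return CorrectedFrame(out, valid)


def screen_corrupted(
    stack: FrameStack, rel_threshold: float = 0.5
) -> tuple[FrameStack, list[int]]:
    """Drop frames whose mean intensity is an outlier for the stack.

    A frame is rejected when its mean deviates from the median of per-frame
    means by more than ``rel_threshold`` as a fraction of that median. This
    catches shutter failures, dropped packets and partial readouts without
    any per-pixel model.
    """
    if not 0.0 < rel_threshold < 1.0:
        raise ValueError("rel_threshold must lie in (0, 1)")
    means = np.array([f.pixels.mean() for f in stack])
    med = float(np.median(means))
    scale = max(abs(med), np.finfo(float).tiny)
    rejected = [
        i for i, m in enumerate(means) if abs(m - med) > rel_threshold * scale
    ]
    survivors = [f for i, f in enumerate(stack) if i not in set(rejected)]
    if not survivors:
        raise ValueError("no usable frames: every frame was rejected as corrupted")
    return FrameStack(survivors), rejected
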