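"""Core frame containers and stack statistics.

Spatial harmonic imaging works from four categories of detector frames:

* ``dark`` — source off; detector offset and read noise only.
* ``bright`` — source on, no mask, no sample; flat-field illumination.
* ``reference`` — mask in the beam, no sample; the periodic mesh pattern.
* ``sample`` — mask and sample; the modulated pattern carrying contrast.

Repeated exposures of one category form a :class:`FrameStack`; averaging the
stack raises the signal-to-noise ratio before Fourier processing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Category",
    "Frame",
    "FrameStack",
    "average_stack",
    "rmse_convergence",
]

MIN_FRAME_DIM = 8


class Category(str, Enum):
    """Acquisition category of a detector frame."""

    DARK = "dark"
    BRIGHT = "bright"
    REFERENCE = "reference"
    SAMPLE = "sample"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class Frame:
    """A single 2-D detector frame in ADU.

    Parameters
    ----------
    pixels
        2-D array of non-negative detector counts. Stored as float64.
    category
        One of the four acquisition categories.
    angle_deg
        CT projection angle; ``None`` for plain projection imaging.
    index
        Repeat index within its stack.
    """

    pixels: np.ndarray
    category: Category
    angle_deg: float | None = None
    index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"frame must be 2-D, got ndim={px.ndim}")
        if min(px.shape) < MIN_FRAME_DIM:
            raise ValueError(
                f"frame dimensions must be >= {MIN_FRAME_DIM}, got {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise ValueError("frame contains non-finite pixel values")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "category", Category(self.category))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "Frame":
        return replace(self, pixels=pixels)


@dataclass
class FrameStack:
    """Ordered collection of same-shape, same-category frames."""

    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("frame stack must contain at least one frame")
        ref = self.frames[0]
        for f in self.frames[1:]:
            if f.shape != ref.shape:
                raise ValueError(
                    f"shape mismatch in stack: {f.shape} != {ref.shape}"
                )
            if f.category != ref.category:
                raise ValueError(
                    f"category mismatch in stack: {f.category} != {ref.category}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def category(self) -> Category:
        return self.frames[0].category

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    def as_array(self) -> np.ndarray:
        """Stack pixels into an (n, rows, cols) float64 array."""
        return np.stack([f.pixels for f in self.frames]).astype(np.float64)


def average_stack(stack: FrameStack) -> Frame:
    """Pixel-wise arithmetic mean of a stack, in double precision.

    The category (and angle, if any) of the first frame is preserved.
    """
    if len(stack) == 0:  # FrameStack forbids this, but guard plain lists
        raise ValueError("cannot average an empty stack")
    mean = stack.as_array().mean(axis=0, dtype=np.float64)
    first = stack[0]
    return Frame(mean, first.category, angle_deg=first.angle_deg, index=0)


def rmse_convergence(stack: FrameStack) -> list[tuple[int, float]]:
    """RMSE between the cumulative mean of the first *n* frames and the full mean.

    Returns ``[(1, rmse_1), ..., (N, 0.0)]``. The last entry is exactly zero
    by construction (the cumulative mean of all N frames *is* the full mean).
    The curve quantifies how quickly frame averaging converges, i.e. how many
    repeats are worth acquiring.
    """
    n_frames = len(stack)
    if n_frames < 2:
        raise ValueError("rmse_convergence requires at least 2 frames")
    arr = stack.as_array()
    cum = np.cumsum(arr, axis=0)
    full_mean = cum[-1] / n_frames
    out: list[tuple[int, float]] = []
    for n in range(1, n_frames + 1):
        cmean = cum[n - 1] / n
        rmse = float(np.sqrt(np.mean((cmean - full_mean) ** 2)))
        out.append((n, rmse))
    # self-comparison is exact, not merely small
    out[-1] = (n_frames, 0.0)
    return out


def make_stack(
    arrays: Sequence[np.ndarray],
    category: Category | str,
    angle_deg: float | None = None,
) -> FrameStack:
    """Convenience constructor: wrap raw arrays into a FrameStack."""
    cat = Category(category)
    return FrameStack(
        [Frame(a, cat, angle_deg=angle_deg, index=i) for i, a in enumerate(arrays)]
    )
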