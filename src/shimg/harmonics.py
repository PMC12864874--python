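"""Fourier harmonic detection, labeling and band-limited extraction.

A periodic mesh (inverted Hartmann mask) multiplies the wavefront by a 2-D
periodic transmission, so the Fourier transform of a corrected frame is a
lattice of peaks at integer multiples of the mask's fundamental frequency.
Each peak (m, n) is a down-modulated copy of the sample's transmission
weighted by the mask's (m, n) Fourier coefficient; cutting a band-limited
window around a peak and inverse-transforming yields the complex *harmonic
image* whose modulus carries amplitude (absorption / visibility) and whose
argument carries the lateral pattern displacement (refraction).

Conventions
-----------
Spectra use the centered convention: the zero-frequency bin sits at
``(rows // 2, cols // 2)``, 0-based. Peak centers are integer bins; sub-bin
mask drift shows up as a linear phase ramp that the reference correction
cancels. The projected mask period ``d`` in detector pixels must satisfy
``d >= 3`` (Nyquist: at least the fundamental and its first alias-free
neighborhood must be resolvable).

Peak detection runs once on a reference (mask-only) spectrum; the resulting
:class:`HarmonicMetadata` is then re-applied verbatim to every further
reference or sample spectrum so sample and reference harmonics always come
from the same Fourier quadrants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .preprocess import CorrectedFrame

__all__ = [
    "NyquistError",
    "MaskNotResolvedError",
    "Spectrum",
    "HarmonicPeak",
    "HarmonicMetadata",
    "HarmonicImage",
    "forward_spectrum",
    "inverse_spectrum",
    "detect_peaks",
    "extract_harmonic",
    "apply_metadata",
]

MIN_PERIOD_PX = 3.0

LABELS: tuple[tuple[int, int], ...] = tuple(
    (m, n) for m in (-1, 0, 1) for n in (-1, 0, 1)
)


class NyquistError(ValueError):
    """Projected mask period below the sampling limit of 3 detector pixels."""


class MaskNotResolvedError(ValueError):
    """Fewer than the nine expected harmonic peaks rise above the noise floor."""


@dataclass
class Spectrum:
    """Centered 2-D discrete Fourier transform of a corrected frame."""

    values: np.ndarray
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2:
            raise ValueError("spectrum must be 2-D")
        if tuple(self.values.shape) != tuple(self.shape):
            raise ValueError("spectrum values do not match recorded source shape")

    @property
    def center(self) -> tuple[int, int]:
        return (self.shape[0] // 2, self.shape[1] // 2)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)


@dataclass(frozen=True)
class HarmonicPeak:
    label: tuple[int, int]
    center_bin: tuple[int, int]
    magnitude: float


@dataclass
class HarmonicMetadata:
    """Reusable description of the harmonic lattice of one reference spectrum."""

    peaks: dict[tuple[int, int], HarmonicPeak]
    band_limit: int
    period_px: float
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.period_px < MIN_PERIOD_PX:
            raise NyquistError(
                f"projected period {self.period_px:.3f} px violates the "
                f"d >= {MIN_PERIOD_PX:g} px sampling limit"
            )
        if self.band_limit < 1:
            raise ValueError("band limit must be at least 1 bin")

    def to_dict(self) -> dict:
        return {
            "band_limit": self.band_limit,
            "period_px": self.period_px,
            "shape": list(self.shape),
            "peaks": [
                {
                    "label": list(p.label),
                    "center_bin": list(p.center_bin),
                    "magnitude": p.magnitude,
                }
                for p in self.peaks.values()
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HarmonicMetadata":
        peaks = {
            tuple(p["label"]): HarmonicPeak(
                tuple(p["label"]), tuple(p["center_bin"]), float(p["magnitude"])
            )
            for p in d["peaks"]
        }
        return cls(
            peaks=peaks,
            band_limit=int(d["band_limit"]),
            period_px=float(d["period_px"]),
            shape=tuple(d["shape"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "HarmonicMetadata":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class HarmonicImage:
    """Complex band-limited harmonic image I_{m,n}(x, y)."""

    label: tuple[int, int]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)

    @property
    def modulus(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def argument(self) -> np.ndarray:
        return np.angle(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


def _as_array(frame) -> np.ndarray:
    if isinstance(frame, CorrectedFrame):
        return frame.pixels
    arr = np.asarray(getattr(frame, "pixels", frame), dtype=np.float64)
    return arr


def forward_spectrum(frame) -> Spectrum:
    """Centered 2-D DFT of a corrected frame (or bare 2-D array)."""
    arr = _as_array(frame)
    if arr.ndim != 2:
        raise ValueError("input must be 2-D")
    if not np.all(np.isfinite(arr)):
        raise ValueError("input contains non-finite values")
    vals = np.fft.fftshift(np.fft.fft2(arr))
    return Spectrum(vals, arr.shape)  # type: ignore[arg-type]


def inverse_spectrum(spectrum: Spectrum) -> np.ndarray:
    """Inverse of :func:`forward_spectrum` (real part of the inverse DFT)."""
    return np.fft.ifft2(np.fft.ifftshift(spectrum.values)).real


def _snap_to_local_max(
    mag: np.ndarray, row: int, col: int, window: int
) -> tuple[int, int]:
    """Move (row, col) to the magnitude maximum within a +/-window box."""
    r0 = max(row - window, 0)
    c0 = max(col - window, 0)
    sub = mag[r0 : row + window + 1, c0 : col + window + 1]
    k = np.unravel_index(int(np.argmax(sub)), sub.shape)
    return (r0 + int(k[0]), c0 + int(k[1]))


def _find_fundamentals_global(
    mag: np.ndarray, center: tuple[int, int], floor: float
) -> tuple[np.ndarray, np.ndarray]:
    """Locate the two first-order lattice vectors with no period hint.

    Brute-force strategy: the strongest non-DC peak in a half-plane is one
    fundamental; the second is the strongest peak not collinear with it.
    """
    rows, cols = mag.shape
    rr, cc = np.mgrid[:rows, :cols]
    dr = rr - center[0]
    dc = cc - center[1]
    half = (dc > 0) | ((dc == 0) & (dr > 0))
    near_dc = dr * dr + dc * dc <= 2 * 2
    cand = np.where(half & ~near_dc, mag, 0.0)
    i1 = np.unravel_index(int(np.argmax(cand)), cand.shape)
    if cand[i1] <= floor:
        raise MaskNotResolvedError(
            "no harmonic peak above the noise floor; mask not resolved"
        )
    q1 = np.array([i1[0] - center[0], i1[1] - center[1]], dtype=float)
    n1 = np.hypot(*q1)
    if n1 == 0:
        raise MaskNotResolvedError("no off-center peak found in spectrum")
    # exclude the q1 axis (and its higher orders / diagonals): a candidate is
    # "collinear" when its perpendicular offset from the q1 line is small
    # relative to its projection along it
    perp = np.abs(dr * q1[1] - dc * q1[0]) / n1
    par = np.abs(dr * q1[0] + dc * q1[1]) / n1
    collinear = perp <= np.maximum(2.0, 0.25 * par)
    cand2 = np.where(half & ~near_dc & ~collinear, mag, 0.0)
    i2 = np.unravel_index(int(np.argmax(cand2)), cand2.shape)
    if cand2[i2] <= floor:
        raise MaskNotResolvedError(
            "second lattice direction not found above the noise floor"
        )
    q2 = np.array([i2[0] - center[0], i2[1] - center[1]], dtype=float)
    return q1, q2


def detect_peaks(
    spectrum: Spectrum,
    expected_period_px: float | None = None,
    noise_floor_rel: float = 1e-3,
    snap_window: int = 2,
) -> HarmonicMetadata:
    """Locate and label the nine harmonics (m, n) in {-1, 0, 1}^2.

    Run this on a *reference* (mask-only) spectrum. The two first-order
    lattice vectors are found either from the expected projected period or by
    a global per-half-plane magnitude search; each of the nine lattice
    positions is then snapped to the local magnitude maximum within a
    ``snap_window``-bin box, compensating residual harmonic displacements
    from source size, sampling and slight mask/detector misalignment.

    The band limit is the floor of half the measured inter-peak spacing, so
    the extraction window edge falls at the midpoint between neighbors.
    """
    if expected_period_px is not None and expected_period_px < MIN_PERIOD_PX:
        raise NyquistError(
            f"requested period {expected_period_px:g} px violates the "
            f"d >= {MIN_PERIOD_PX:g} px sampling limit"
        )
    mag = spectrum.magnitude
    rows, cols = spectrum.shape
    center = spectrum.center
    floor = noise_floor_rel * mag[center]

    if expected_period_px is not None:
        k_r = rows / expected_period_px
        k_c = cols / expected_period_px
        win_r = max(snap_window, int(round(k_r / 4)))
        win_c = max(snap_window, int(round(k_c / 4)))
        p_row = _snap_to_local_max(
            mag, center[0] + int(round(k_r)), center[1], win_r
        )
        p_col = _snap_to_local_max(
            mag, center[0], center[1] + int(round(k_c)), win_c
        )
        q_row = np.array([p_row[0] - center[0], p_row[1] - center[1]], float)
        q_col = np.array([p_col[0] - center[0], p_col[1] - center[1]], float)
    else:
        q1, q2 = _find_fundamentals_global(mag, center, floor)
        # assign row/column roles by dominant component
        if abs(q1[0]) >= abs(q1[1]):
            q_row, q_col = q1, q2
        else:
            q_row, q_col = q2, q1
        if abs(q_row[0]) < abs(q_row[1]) or abs(q_col[1]) < abs(q_col[0]):
            raise MaskNotResolvedError(
                "detected lattice vectors do not separate into row/column "
                "fundamentals; mask pattern not resolved"
            )
    # orient: (1,0) increases row frequency, (0,1) increases column frequency
    if q_row[0] < 0:
        q_row = -q_row
    if q_col[1] < 0:
        q_col = -q_col

    d_row = rows / float(np.hypot(*q_row))
    d_col = cols / float(np.hypot(*q_col))
    period = min(d_row, d_col)
    if period < MIN_PERIOD_PX:
        raise NyquistError(
            f"measured projected period {period:.3f} px violates the "
            f"d >= {MIN_PERIOD_PX:g} px sampling limit (mask not resolved)"
        )

    peaks: dict[tuple[int, int], HarmonicPeak] = {}
    missing: list[tuple[int, int]] = []
    for m, n in LABELS:
        pr = center[0] + m * q_row[0] + n * q_col[0]
        pc = center[1] + m * q_row[1] + n * q_col[1]
        r, c = _snap_to_local_max(
            mag, int(round(pr)), int(round(pc)), snap_window
        )
        magnitude = float(mag[r, c])
        if (m, n) != (0, 0) and magnitude <= floor:
            missing.append((m, n))
        peaks[(m, n)] = HarmonicPeak((m, n), (r, c), magnitude)
    if missing:
        raise MaskNotResolvedError(
            f"harmonic peaks below noise floor: {missing}; mask not resolved"
        )
    peaks[(0, 0)] = HarmonicPeak((0, 0), center, float(mag[center]))

    spacing = min(float(np.hypot(*q_row)), float(np.hypot(*q_col)))
    band_limit = int(np.floor(spacing / 2.0))
    return HarmonicMetadata(
        peaks=peaks,
        band_limit=band_limit,
        period_px=float(period),
        shape=(rows, cols),
    )


def extract_harmonic(
    spectrum: Spectrum, peak: HarmonicPeak, band_limit: int
) -> HarmonicImage:
    """Cut the band-limited window around a peak and inverse-transform it.

    The square window of side ``2 * band_limit + 1`` centered on the peak is
    re-centered onto zero frequency and inverse-transformed, demodulating the
    harmonic carrier. All harmonics extracted with one band limit share the
    window size, hence identical harmonic-image dimensions. Values are scaled
    so the (0, 0) harmonic of a constant image equals that constant.
    """
    side = 2 * band_limit + 1
    r, c = peak.center_bin
    rows, cols = spectrum.shape
    if (
        r - band_limit < 0
        or c - band_limit < 0
        or r + band_limit >= rows
        or c + band_limit >= cols
    ):
        raise ValueError(
            f"band-limit window of side {side} around bin {peak.center_bin} "
            f"exceeds the spectrum bounds {spectrum.shape}; use a smaller band limit"
        )
    window = spectrum.values[
        r - band_limit : r + band_limit + 1, c - band_limit : c + band_limit + 1
    ]
    values = np.fft.ifft2(np.fft.ifftshift(window)) * (side * side / (rows * cols))
    return HarmonicImage(peak.label, values)


def apply_metadata(
    spectrum: Spectrum, meta: HarmonicMetadata
) -> dict[tuple[int, int], HarmonicImage]:
    """Extract all nine harmonics at previously detected centers.

    This is the normal path for sample spectra (and repeat references): the
    lattice is measured once on a clean reference and reused, guaranteeing
    sample and reference harmonics occupy the same Fourier quadrants.
    """
    if tuple(spectrum.shape) != tuple(meta.shape):
        raise ValueError(
            f"spectrum shape {spectrum.shape} does not match metadata shape {meta.shape}"
        )
    return {
        label: extract_harmonic(spectrum, peak, meta.band_limit)
        for label, peak in meta.peaks.items()
    }
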