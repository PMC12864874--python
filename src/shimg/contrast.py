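"""Reference correction and multicontrast retrieval.

Each harmonic image factorizes as ``I_{m,n} = I_0 · D_{m,n} · exp(i ψ_{m,n})``
with ``I_0`` the transmitted intensity, ``D`` the visibility (scattering)
amplitude and ``ψ`` the lateral-displacement phase. Dividing a sample
harmonic by the matching reference harmonic cancels the mask and the
illumination, leaving the sample-only factors. From the ratios:

* absorption  ``A = -ln |I^S_00 / I^R_00|``  (Beer–Lambert optical thickness
  µ·d for a pure absorber; the (0,0) harmonic carries no mask modulation, so
  D = 1 and ψ = 0 there);
* scattering (dark-field)
  ``S_mn = -ln [ (|I^S_mn| / |I^S_00|) / (|I^R_mn| / |I^R_00|) ]``
  — the log visibility loss of harmonic (m,n), absorption cancelling through
  the (0,0) normalization;
* differential phase  ``P_mn = arg (I^S_mn / I^R_mn)`` in (−π, π], equal to
  ``2π δ / d`` for a rigid pattern displacement δ along the (m,n) direction
  with projected period d.

The same formulas at (±1, ±1) give the diagonal (second-order) channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from skimage.restoration import unwrap_phase as _skimage_unwrap

from .harmonics import HarmonicImage

__all__ = [
    "RatioField",
    "ContrastSet",
    "reference_correct",
    "absorption",
    "scattering",
    "dpc",
    "combine_directions",
    "unwrap",
    "register_unwrap_method",
    "available_unwrap_methods",
    "retrieve_contrasts",
]

DEFAULT_GUARD = 1e-3

FIRST_ORDER_LABELS = ((0, 1), (0, -1), (1, 0), (-1, 0))
SECOND_ORDER_LABELS = ((1, 1), (1, -1), (-1, 1), (-1, -1))


@dataclass
class RatioField:
    """Pixel-wise complex ratio I^S_{m,n} / I^R_{m,n} with validity mask."""

    label: tuple[int, int]
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("ratio values and mask must share a shape")


@dataclass
class ContrastSet:
    """Retrieved contrast maps for one sample image.

    ``scattering`` and ``phase`` are keyed by harmonic label; masks flag the
    pixels where the reference harmonic was strong enough to divide by.
    """

    absorption: np.ndarray
    scattering: dict[tuple[int, int], np.ndarray]
    phase: dict[tuple[int, int], np.ndarray]
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def bidirectional_scattering(self) -> np.ndarray:
        """Mean of the horizontal (0,1) and vertical (1,0) dark-field maps."""
        return combine_directions(self.scattering[(1, 0)], self.scattering[(0, 1)])

    def bidirectional_phase(self) -> np.ndarray:
        return combine_directions(self.phase[(1, 0)], self.phase[(0, 1)])


def reference_correct(
    sample_h: HarmonicImage, ref_h: HarmonicImage, guard: float = DEFAULT_GUARD
) -> RatioField:
    """Divide matching sample and reference harmonics pixel-wise.

    Pixels where the reference modulus falls below ``guard`` times its
    maximum are masked invalid (a near-zero reference harmonic carries no
    usable signal and would blow up the ratio).
    """
    if sample_h.label != ref_h.label:
        raise ValueError(
            f"harmonic label mismatch: sample {sample_h.label} vs reference {ref_h.label}"
        )
    if sample_h.shape != ref_h.shape:
        raise ValueError("sample and reference harmonic shapes differ")
    if guard <= 0:
        raise ValueError("guard must be positive")
    ref_mod = ref_h.modulus
    valid = ref_mod > guard * float(ref_mod.max())
    out = np.zeros_like(sample_h.values)
    np.divide(sample_h.values, ref_h.values, out=out, where=valid)
    return RatioField(sample_h.label, out, valid)


def absorption(ratio00: RatioField) -> np.ndarray:
    """Absorption map ``A = -ln |ratio|`` from the (0, 0) harmonic ratio.

    For a pure absorber this is the Beer–Lambert optical thickness µ·d.
    Non-positive ratios (real part <= 0, i.e. unphysical sign flips) are
    masked to zero in place; consult ``valid_absorption_mask`` for them.
    """
    if ratio00.label != (0, 0):
        raise ValueError(f"absorption requires the (0, 0) ratio, got {ratio00.label}")
    mod = np.abs(ratio00.values)
    valid = ratio00.valid & (ratio00.values.real > 0) & (mod > 0)
    out = np.zeros(mod.shape, dtype=np.float64)
    np.log(mod, out=out, where=valid)
    out = -out
    out[~valid] = 0.0
    return out


def valid_absorption_mask(ratio00: RatioField) -> np.ndarray:
    return ratio00.valid & (ratio00.values.real > 0) & (np.abs(ratio00.values) > 0)


def scattering(
    ratio_mn: RatioField,
    sample00: HarmonicImage,
    ref00: HarmonicImage,
) -> np.ndarray:
    """Dark-field map ``S = -ln`` of the visibility ratio at harmonic (m, n).

    The first-harmonic modulus is normalized by the (0, 0) modulus of the
    same image before taking the sample/reference ratio, so pure absorption
    cancels and only visibility loss (sub-pixel small-angle scatter) remains.
    Valid at first-order (0, ±1), (±1, 0) and diagonal (±1, ±1) labels.
    """
    if ratio_mn.label == (0, 0):
        raise ValueError(
            "scattering is undefined at the (0, 0) harmonic: the fundamental "
            "carries no mask modulation (D_00 = 1)"
        )
    if sample00.label != (0, 0) or ref00.label != (0, 0):
        raise ValueError("sample00 and ref00 must be the (0, 0) harmonics")
    s00 = np.abs(sample00.values)
    r00 = np.abs(ref00.values)
    # |ratio_mn| = |I^S_mn| / |I^R_mn|; multiply by |I^R_00| / |I^S_00|
    vis_ratio = np.abs(ratio_mn.values) * r00
    valid = ratio_mn.valid & (s00 > 0) & (vis_ratio > 0)
    denom = np.where(s00 > 0, s00, 1.0)
    vis_ratio = vis_ratio / denom
    out = np.zeros(vis_ratio.shape, dtype=np.float64)
    np.log(vis_ratio, out=out, where=valid & (vis_ratio > 0))
    out = -out
    out[~valid] = 0.0
    return out


def dpc(ratio_mn: RatioField) -> np.ndarray:
    """Differential phase map ``P = arg(ratio)`` in (−π, π] at harmonic (m, n)."""
    if ratio_mn.label == (0, 0):
        raise ValueError(
            "differential phase is undefined at the (0, 0) harmonic (ψ_00 = 0)"
        )
    out = np.angle(ratio_mn.values)
    out[~ratio_mn.valid] = 0.0
    return out


def combine_directions(map_h: np.ndarray, map_v: np.ndarray) -> np.ndarray:
    """Pixel-wise mean of the two directional maps (bidirectional contrast)."""
    map_h = np.asarray(map_h, dtype=np.float64)
    map_v = np.asarray(map_v, dtype=np.float64)
    if map_h.shape != map_v.shape:
        raise ValueError(f"shape mismatch: {map_h.shape} vs {map_v.shape}")
    return 0.5 * (map_h + map_v)


def _unwrap_none(p: np.ndarray) -> np.ndarray:
    return np.array(p, dtype=np.float64, copy=True)


def _unwrap_quality(p: np.ndarray) -> np.ndarray:
    # reliability-sorted 2-D unwrapper
    return np.asarray(_skimage_unwrap(np.asarray(p, dtype=np.float64)))


_UNWRAP_REGISTRY: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "none": _unwrap_none,
    "quality": _unwrap_quality,
}


def register_unwrap_method(
    name: str, fn: Callable[[np.ndarray], np.ndarray]
) -> None:
    """Register a user phase-unwrapping plug-in under ``name``."""
    _UNWRAP_REGISTRY[name] = fn


def available_unwrap_methods() -> list[str]:
    return sorted(_UNWRAP_REGISTRY)


def unwrap(phase_map: np.ndarray, method: str = "none") -> np.ndarray:
    """Unwrap a phase map; output is congruent to the input modulo 2π."""
    try:
        fn = _UNWRAP_REGISTRY[method]
    except KeyError:
        raise ValueError(
            f"unknown unwrap method {method!r}; available: {available_unwrap_methods()}"
        ) from None
    return fn(np.asarray(phase_map, dtype=np.float64))


def retrieve_contrasts(
    sample_harmonics: dict[tuple[int, int], HarmonicImage],
    reference_harmonics: dict[tuple[int, int], HarmonicImage],
    guard: float = DEFAULT_GUARD,
    unwrap_method: str = "none",
) -> ContrastSet:
    """Full contrast retrieval from matched harmonic-image dictionaries."""
    ratios = {
        label: reference_correct(sample_harmonics[label], reference_harmonics[label], guard)
        for label in sample_harmonics
        if label in reference_harmonics
    }
    if (0, 0) not in ratios:
        raise ValueError("the (0, 0) harmonic is required for contrast retrieval")
    a_map = absorption(ratios[(0, 0)])
    s_maps: dict[tuple[int, int], np.ndarray] = {}
    p_maps: dict[tuple[int, int], np.ndarray] = {}
    masks: dict[str, np.ndarray] = {
        "absorption": valid_absorption_mask(ratios[(0, 0)])
    }
    for label in FIRST_ORDER_LABELS + SECOND_ORDER_LABELS:
        if label not in ratios:
            continue
        s_maps[label] = scattering(
            ratios[label], sample_harmonics[(0, 0)], reference_harmonics[(0, 0)]
        )
        p_maps[label] = unwrap(dpc(ratios[label]), unwrap_method)
        masks[f"harmonic_{label[0]:+d}{label[1]:+d}"] = ratios[label].valid
    return ContrastSet(
        absorption=a_map, scattering=s_maps, phase=p_maps, masks=masks
    )
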