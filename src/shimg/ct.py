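"""Computed-tomography preparation and reconstruction.

The acquisition geometry is a cone beam (point source), but with the mask in
the beam the resolution delivered to the sample plane is set by the mask
period projected onto it, which suppresses magnification differences below
the harmonic band limit. Two quantities matter:

* the *mask-limited effective pixel* ``p_eff = p_detector · D2 / D1`` for an
  optic placed upstream of the sample at distance D1 from the source (sample
  at D2): the mask period projected from the optic plane to the sample plane
  grows by D2/D1, so that is the sampling the harmonics impose there;
* the *geometric sample-plane pixel* ``p_detector · D2 / Dsd`` — the plain
  cone-beam demagnification of a detector pixel back to the sample.

Projections can be rebinned from the diverging geometry onto parallel-ray
coordinates before reconstruction; at laboratory distances the correction is
small, which is why parallel filtered backprojection on raw projections is
already accurate. Reconstruction here is classical parallel-beam FBP with
the Ram-Lak (ramp) filter; only the rotation center is needed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.metrics import (
    normalized_mutual_information,
    structural_similarity,
)
from skimage.transform import iradon

from .io import ProjectLayout, list_angle_indices, load_map

__all__ = [
    "Geometry",
    "Sinogram",
    "MetricsReport",
    "effective_pixel_size",
    "sample_plane_pixel_size",
    "rebin_cone_to_parallel",
    "is_rebinned",
    "assemble_sinogram",
    "fbp_reconstruct",
    "quality_metrics",
    "projection_count_study",
]

logger = logging.getLogger(__name__)

MIN_PERIOD_PX = 3.0


@dataclass(frozen=True)
class Geometry:
    """Source-centered distances (cm) and detector/mask scales (µm).

    ``d1``: source → optic (mask); ``d2``: source → sample; ``dsd``: source →
    detector. The validated configuration places the optic upstream of the
    sample (``d1 <= d2``); the reversed order is admitted with
    ``optic_upstream=False``.
    """

    d1: float
    d2: float
    dsd: float
    pixel_um: float
    mask_period_um: float | None = None
    optic_upstream: bool = True

    def __post_init__(self) -> None:
        if min(self.d1, self.d2, self.dsd) <= 0 or self.pixel_um <= 0:
            raise ValueError("geometry distances and pixel size must be positive")
        if self.optic_upstream and not (self.d1 <= self.d2 < self.dsd):
            raise ValueError(
                "expected 0 < d1 <= d2 < dsd for an optic upstream of the sample"
            )
        if not self.optic_upstream and not (self.d2 <= self.d1 < self.dsd):
            raise ValueError(
                "expected 0 < d2 <= d1 < dsd for an optic downstream of the sample"
            )

    @property
    def projected_period_px(self) -> float | None:
        """Mask period as imaged on the detector, in detector pixels."""
        if self.mask_period_um is None:
            return None
        optic_dist = self.d1 if self.optic_upstream else self.d1
        return self.mask_period_um * (self.dsd / optic_dist) / self.pixel_um

    def validate_sampling(self) -> None:
        d = self.projected_period_px
        if d is not None and d < MIN_PERIOD_PX:
            raise ValueError(
                f"projected mask period {d:.3f} px violates the "
                f"d >= {MIN_PERIOD_PX:g} px sampling limit"
            )


def effective_pixel_size(geom: Geometry) -> float:
    """Mask-limited effective pixel size at the sample plane, in µm.

    The mask period projected from the optic plane (distance D1) to the
    sample plane (distance D2) scales by D2/D1 in the diverging beam, so a
    detector pixel referred to the mask-limited sampling grid measures
    ``p_detector · D2 / D1`` (ratio inverted when the optic sits downstream).
    The ratio is always >= 1: the mask coarsens, never refines, the sampling.
    """
    ratio = geom.d2 / geom.d1 if geom.optic_upstream else geom.d1 / geom.d2
    logger.debug(
        "effective pixel: p=%g um, ratio=%g (optic %s)",
        geom.pixel_um,
        ratio,
        "upstream" if geom.optic_upstream else "downstream",
    )
    return geom.pixel_um * ratio


def sample_plane_pixel_size(geom: Geometry) -> float:
    """Geometric (cone-beam demagnified) detector pixel at the sample, in µm."""
    return geom.pixel_um * geom.d2 / geom.dsd


class _RebinnedArray(np.ndarray):
    """Marker subclass recording that a projection was already rebinned."""


def is_rebinned(arr: np.ndarray) -> bool:
    return isinstance(arr, _RebinnedArray)


def rebin_cone_to_parallel(projection: np.ndarray, geom: Geometry) -> np.ndarray:
    """Remap a cone-beam projection onto parallel-ray sample-plane coordinates.

    A detector position (u, v) measured from the principal ray sees the ray
    whose parallel coordinate at the sample is ``t = u · D2 / sqrt(Dsd² + u²
    + v²)`` (and symmetrically for v). The output is resampled on a regular
    grid of those parallel coordinates expressed in detector-pixel units
    (``t_px = u_px · Dsd / sqrt(Dsd² + u² + v²)``), so the map tends to the
    identity as Dsd → ∞. Bilinear interpolation; output shape = input shape.

    Applying the operation twice is an error: the output array carries a
    provenance marker checked on entry.
    """
    if is_rebinned(projection):
        raise ValueError("projection was already rebinned; refusing to rebin twice")
    proj = np.asarray(projection, dtype=np.float64)
    if proj.ndim != 2:
        raise ValueError("projection must be 2-D")
    if not np.all(np.isfinite(proj)):
        raise ValueError("projection contains non-finite values")
    rows, cols = proj.shape
    p_cm = geom.pixel_um * 1e-4
    dsd = geom.dsd
    cr, cc = (rows - 1) / 2.0, (cols - 1) / 2.0
    t_r = (np.arange(rows) - cr) * p_cm  # parallel coords of output grid, cm
    t_c = (np.arange(cols) - cc) * p_cm
    b, a = np.meshgrid(t_r, t_c, indexing="ij")
    q2 = a * a + b * b
    q2 = np.minimum(q2, (dsd * 0.999999) ** 2)
    # invert t(u, v): radial distances satisfy s = q · Dsd / sqrt(Dsd² - q²)
    scale = dsd / np.sqrt(dsd * dsd - q2)
    u = a * scale
    v = b * scale
    coords = np.stack([v / p_cm + cr, u / p_cm + cc])
    out = ndimage.map_coordinates(proj, coords, order=1, mode="nearest")
    return out.view(_RebinnedArray)


@dataclass
class Sinogram:
    """Angle-ordered projection stack for one harmonic/contrast channel."""

    values: np.ndarray  # (n_angles, cols) or (n_angles, rows, cols)
    angles_deg: np.ndarray
    label: tuple[int, int] | None = None
    kind: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        if len(self.angles_deg) != self.values.shape[0]:
            raise ValueError("angle count does not match projection count")
        if len(self.angles_deg) < 2:
            raise ValueError("a sinogram needs at least 2 angles")
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ValueError("angles must be strictly increasing")

    @property
    def n_angles(self) -> int:
        return int(self.values.shape[0])

    def slice(self, row: int) -> "Sinogram":
        """Extract the (angle × detector-col) sinogram of one detector row."""
        if self.values.ndim != 3:
            raise ValueError("slice() applies to 3-D sinograms")
        return Sinogram(self.values[:, row, :], self.angles_deg, self.label, self.kind)


def assemble_sinogram(
    layout: ProjectLayout, label: tuple[int, int], kind: str
) -> Sinogram:
    """Collect per-angle contrast images into an angle-sorted sinogram.

    Angle indices are parsed from the ``angle_#####`` file names, so on-disk
    ordering is irrelevant. A gap in the index sequence (a missing angle) is
    an error naming the offending angle.
    """
    cdir = layout.contrast_dir(label, kind)
    files = sorted(cdir.glob("angle_*.tif"))
    if not files:
        raise FileNotFoundError(f"no projections found under {cdir}")
    indices = list_angle_indices(files)
    meta = layout.read_scan_meta() if layout.scan_meta_path.exists() else {}
    n_angles = int(meta.get("n_angles", len(indices)))
    span = float(meta.get("angle_span_deg", 180.0))
    expected = list(range(n_angles))
    missing = sorted(set(expected) - set(indices))
    if missing:
        raise FileNotFoundError(
            f"missing projection angle index {missing[0]} "
            f"({missing[0] * span / n_angles:.3f} deg) in {cdir}"
        )
    by_index = {i: f for i, f in zip(indices, files)}
    maps = []
    shape = None
    for i in expected:
        arr = load_map(by_index[i])
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValueError(
                f"projection shape mismatch at angle index {i}: {arr.shape} != {shape}"
            )
        maps.append(arr)
    angles = np.array(expected) * span / n_angles
    return Sinogram(np.stack(maps), angles, label=label, kind=kind)


def fbp_reconstruct(
    sino: Sinogram | np.ndarray,
    center: float | None = None,
    filter_name: str = "ramlak",
    angles_deg: np.ndarray | None = None,
) -> np.ndarray:
    """Parallel-beam filtered backprojection of one sinogram slice.

    Per-angle ramp (Ram-Lak) filtering along the detector axis followed by
    backprojection. ``center`` is the rotation-axis position in detector
    pixels (default: detector midpoint); the sinogram is shifted so the axis
    sits where the backprojector expects it. Output is a square slice with
    side equal to the detector width. Linear in the sinogram.
    """
    if filter_name not in ("ramlak", "ramp"):
        raise ValueError(f"unknown filter {filter_name!r}; available: ramlak")
    if isinstance(sino, Sinogram):
        values = sino.values
        angles = sino.angles_deg
    else:
        values = np.asarray(sino, dtype=np.float64)
        if angles_deg is None:
            raise ValueError("angles_deg required when passing a bare array")
        angles = np.asarray(angles_deg, dtype=np.float64)
    if values.ndim != 2:
        raise ValueError("fbp_reconstruct expects a 2-D (angle x detector) sinogram")
    if values.shape[0] < 2:
        raise ValueError("at least 2 angles are required")
    width = values.shape[1]
    if center is None:
        center = width // 2
    if not 0 <= center < width:
        raise ValueError(f"rotation center {center} outside detector [0, {width})")
    shift = width // 2 - float(center)
    if shift != 0.0:
        values = ndimage.shift(values, (0.0, shift), order=1, mode="nearest")
    # skimage expects (detector, angles)
    recon = iradon(
        values.T,
        theta=angles,
        filter_name="ramp",
        interpolation="linear",
        circle=True,
        output_size=width,
    )
    return np.asarray(recon, dtype=np.float64)


PSNR_INF = float("inf")


@dataclass(frozen=True)
class MetricsReport:
    """Reconstruction-quality metrics of one comparison against a reference."""

    nrmse: float
    psnr_db: float
    mssim: float
    nmi: float
    n_projections: int | None = None

    def as_dict(self) -> dict:
        return {
            "n_projections": self.n_projections,
            "nrmse": self.nrmse,
            "psnr_db": self.psnr_db,
            "mssim": self.mssim,
            "nmi": self.nmi,
        }


def quality_metrics(
    recon: np.ndarray,
    reference: np.ndarray,
    n_projections: int | None = None,
    bins: int = 256,
) -> MetricsReport:
    """NRMSE, PSNR, MSSIM and NMI of ``recon`` against ``reference``.

    * NRMSE = RMSE / (max − min of reference);
    * PSNR = 10·log10(range² / MSE) in dB (+∞ for an exact match);
    * MSSIM = mean local SSIM, 7×7 window, constants on the reference range;
    * NMI = (H(X) + H(Y)) / H(X, Y), 256-bin histograms, in [1, 2].
    """
    recon = np.asarray(recon, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if recon.shape != reference.shape:
        raise ValueError(
            f"shape mismatch: recon {recon.shape} vs reference {reference.shape}"
        )
    data_range = float(reference.max() - reference.min())
    if data_range == 0.0:
        raise ValueError("reference image is constant; NRMSE is undefined")
    mse = float(np.mean((recon - reference) ** 2))
    nrmse = math.sqrt(mse) / data_range
    psnr = PSNR_INF if mse == 0.0 else 10.0 * math.log10(data_range**2 / mse)
    # 7x7 local window; shrink (odd) for images smaller than the window
    win = min(7, min(reference.shape) - (1 - min(reference.shape) % 2))
    mssim = float(
        structural_similarity(
            reference, recon, win_size=win, data_range=data_range
        )
    )
    nmi = float(normalized_mutual_information(reference, recon, bins=bins))
    return MetricsReport(
        nrmse=nrmse,
        psnr_db=psnr,
        mssim=mssim,
        nmi=nmi,
        n_projections=n_projections,
    )


def decimate_angles(n_full: int, count: int) -> np.ndarray:
    """Evenly spaced angle-index subset of size ``count`` including index 0."""
    if count > n_full:
        raise ValueError(f"requested {count} projections but only {n_full} available")
    if count < 2:
        raise ValueError("at least 2 projections are required")
    return np.unique((np.arange(count) * n_full // count).astype(int))


def projection_count_study(
    full_sino: Sinogram, counts: list[int], center: float | None = None
) -> list[MetricsReport]:
    """Reconstruction quality versus number of projections.

    For each requested count N the angles are evenly decimated (always
    keeping angle 0), the slice is reconstructed and the four metrics are
    computed against the full-count reconstruction. Results are returned
    sorted by N regardless of input order.
    """
    reference = fbp_reconstruct(full_sino, center=center)
    n_full = full_sino.n_angles
    reports = []
    for count in sorted(set(int(c) for c in counts)):
        idx = decimate_angles(n_full, count)
        sub = Sinogram(
            full_sino.values[idx],
            full_sino.angles_deg[idx],
            full_sino.label,
            full_sino.kind,
        )
        recon = fbp_reconstruct(sub, center=center)
        reports.append(quality_metrics(recon, reference, n_projections=count))
    return reports
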