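"""Synthetic forward model of a spatial-harmonic-imaging measurement.

Generates the four frame categories (dark, bright, reference, sample) — and
whole CT scans — from a ground-truth phantom, so the entire retrieval
pipeline can be exercised and validated offline against known parameters.

Forward model of a sample frame, applied to the rendered mask pattern in
order:

1. warp by the local beamlet-displacement field (``shift_x``, ``shift_y``)
   — the refraction proxy sensed by the differential-phase channel;
2. multiply by ``exp(-mu_d)`` — Beer–Lambert attenuation, sensed by the
   absorption channel;
3. convolve with a Gaussian of width ``sigma`` (piecewise constant per
   phantom region) — visibility loss from sub-pixel small-angle scatter,
   sensed by the dark-field channel. A Gaussian diffuser of width σ reduces
   the first-harmonic amplitude by exp(−2π²σ²/d²), i.e. S = 2π²σ²/d² for
   projected period d;
4. multiply by the flat-field gain map, scale to the photon level, apply
   Poisson (shot) noise, add the detector dark offset and Gaussian read
   noise.

All four categories share the gain, offset and noise model, and everything
is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
from scipy import ndimage

from .ct import Geometry
from .datamodel import Category, Frame, FrameStack
from .io import ProjectLayout, frame_filename, init_project, save_frame, save_map

__all__ = [
    "MaskSpec",
    "PhantomSpec",
    "PhantomVolume",
    "SimConfig",
    "render_mask",
    "render_frames",
    "simulate_ct",
    "disk_phantom",
    "trimodal_phantom",
    "cylinder_volume",
]

MIN_PERIOD_PX = 3.0


@dataclass(frozen=True)
class MaskSpec:
    """Projected inverted-Hartmann-mask pattern parameters.

    ``period``: projected period in detector pixels (>= 3, Nyquist);
    ``duty``: opaque-pillar fraction of each period along each axis;
    ``transmission``: residual transmission of a pillar;
    ``offset``: lateral pattern offset in pixels (row, col).
    """

    period: float = 8.0
    duty: float = 0.5
    transmission: float = 0.05
    offset: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.period < MIN_PERIOD_PX:
            raise ValueError(
                f"mask period {self.period:g} px violates the "
                f"d >= {MIN_PERIOD_PX:g} px sampling limit"
            )
        if not 0.0 < self.duty < 1.0:
            raise ValueError("duty cycle must lie in (0, 1)")
        if not 0.0 <= self.transmission < 1.0:
            raise ValueError("pillar transmission must lie in [0, 1)")


def _axis_profile(n: int, period: float, duty: float, trans: float, off: float) -> np.ndarray:
    frac = np.mod(np.arange(n, dtype=np.float64) - off, period) / period
    return np.where(frac < duty, trans, 1.0)


def render_mask(mask: MaskSpec, shape: tuple[int, int]) -> np.ndarray:
    """Separable periodic transmission pattern in [transmission, 1].

    Along each axis a fraction ``duty`` of every period transmits
    ``transmission`` (pillar) and the rest transmits 1 (gap), so the per-axis
    mean over a whole period is ``(1 - duty) + duty * transmission``.
    """
    ty = _axis_profile(shape[0], mask.period, mask.duty, mask.transmission, mask.offset[0])
    tx = _axis_profile(shape[1], mask.period, mask.duty, mask.transmission, mask.offset[1])
    return np.outer(ty, tx)


@dataclass
class PhantomSpec:
    """Ground-truth maps driving the sample forward model.

    ``mu_d``: optical thickness µ·d (dimensionless, >= 0);
    ``shift_x``/``shift_y``: beamlet displacement at the detector in pixels
    (|shift| < period/2 keeps the phase channel unwrapped);
    ``sigma``: Gaussian scatter-blur width in pixels (>= 0, piecewise
    constant per region).
    """

    mu_d: np.ndarray
    shift_x: np.ndarray
    shift_y: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        maps = {}
        for name in ("mu_d", "shift_x", "shift_y", "sigma"):
            maps[name] = np.asarray(getattr(self, name), dtype=np.float64)
            setattr(self, name, maps[name])
        shapes = {m.shape for m in maps.values()}
        if len(shapes) != 1:
            raise ValueError("all phantom maps must share one shape")
        if np.any(maps["mu_d"] < 0) or np.any(maps["sigma"] < 0):
            raise ValueError("mu_d and sigma must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mu_d.shape  # type: ignore[return-value]

    @classmethod
    def null(cls, shape: tuple[int, int]) -> "PhantomSpec":
        z = np.zeros(shape)
        return cls(z.copy(), z.copy(), z.copy(), z.copy())


def disk_phantom(
    shape: tuple[int, int],
    radius: float | None = None,
    center: tuple[float, float] | None = None,
    mu_d: float = 0.7,
    shift: tuple[float, float] = (0.0, 0.0),
    sigma: float = 0.0,
) -> PhantomSpec:
    """Uniform disk phantom: constant µ·d, shift and σ inside a disk."""
    if radius is None:
        radius = min(shape) * 0.3
    if center is None:
        center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    inside = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
    p = PhantomSpec.null(shape)
    p.mu_d[inside] = mu_d
    p.shift_x[inside] = shift[1]
    p.shift_y[inside] = shift[0]
    p.sigma[inside] = sigma
    return p


def trimodal_phantom(
    shape: tuple[int, int],
    mu_d: float = 0.7,
    shift_px: float = 1.0,
    sigma: float = 1.0,
) -> PhantomSpec:
    """Three disjoint disks, one per contrast channel (absorber, refractor,
    diffuser), for qualitative end-to-end demonstrations."""
    p = PhantomSpec.null(shape)
    r = min(shape) * 0.15
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    centers = [
        (shape[0] * 0.3, shape[1] * 0.3),
        (shape[0] * 0.3, shape[1] * 0.7),
        (shape[0] * 0.72, shape[1] * 0.5),
    ]
    masks = [
        (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2 for cy, cx in centers
    ]
    p.mu_d[masks[0]] = mu_d
    p.shift_x[masks[1]] = shift_px
    p.sigma[masks[2]] = sigma
    return p


def _default_gain(shape: tuple[int, int]) -> np.ndarray:
    # smooth, ~10% peak-to-peak illumination/gain structure
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    gy = (yy - shape[0] / 2) / shape[0]
    gx = (xx - shape[1] / 2) / shape[1]
    return 1.0 + 0.05 * np.cos(2 * np.pi * gx) * np.cos(2 * np.pi * gy)


@dataclass(frozen=True)
class SimConfig:
    """Detector and exposure model shared by all frame categories.

    ``photons``: mean photon count per pixel at the bright level (Poisson
    scale); ``dark_offset``: detector offset in ADU; ``read_noise``:
    Gaussian read-noise standard deviation in ADU; ``noise=False`` renders
    the noiseless expectation (no Poisson, no read noise); ``n_frames``:
    repeats per category.
    """

    shape: tuple[int, int] = (512, 512)
    photons: float = 1e4
    dark_offset: float = 100.0
    read_noise: float = 2.0
    gain: np.ndarray | Callable[[tuple[int, int]], np.ndarray] | None = None
    n_frames: int = 1
    noise: bool = True
    seed: int = 0
    geometry: Geometry | None = None

    def __post_init__(self) -> None:
        if self.photons <= 0:
            raise ValueError("photon count must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    def gain_map(self) -> np.ndarray:
        if self.gain is None:
            return _default_gain(self.shape)
        if callable(self.gain):
            return np.asarray(self.gain(self.shape), dtype=np.float64)
        return np.asarray(self.gain, dtype=np.float64)


def apply_phantom(pattern: np.ndarray, phantom: PhantomSpec) -> np.ndarray:
    """Warp, attenuate and blur the mask pattern per the ground-truth maps."""
    if pattern.shape != phantom.shape:
        raise ValueError(
            f"phantom shape {phantom.shape} does not match frame shape {pattern.shape}"
        )
    yy, xx = np.mgrid[: pattern.shape[0], : pattern.shape[1]].astype(np.float64)
    # a beamlet displaced by +s appears at x: sample the pattern at x - s
    coords = np.stack([yy - phantom.shift_y, xx - phantom.shift_x])
    warped = ndimage.map_coordinates(pattern, coords, order=1, mode="grid-wrap")
    attenuated = warped * np.exp(-phantom.mu_d)
    sigmas = np.unique(phantom.sigma)
    out = attenuated
    for s in sigmas:
        if s <= 0:
            continue
        blurred = ndimage.gaussian_filter(attenuated, s, mode="wrap")
        out = np.where(phantom.sigma == s, blurred, out)
    return out


def _ideal_signal(
    category: Category, mask: MaskSpec | None, phantom: PhantomSpec | None,
    shape: tuple[int, int],
) -> np.ndarray:
    if category == Category.DARK:
        return np.zeros(shape)
    if category == Category.BRIGHT:
        return np.ones(shape)
    assert mask is not None
    pattern = render_mask(mask, shape)
    if category == Category.REFERENCE:
        return pattern
    return apply_phantom(pattern, phantom if phantom is not None else PhantomSpec.null(shape))


def render_frames(
    mask: MaskSpec | None,
    phantom: PhantomSpec | None,
    cfg: SimConfig,
    categories: tuple[str, ...] = ("dark", "bright", "reference", "sample"),
) -> dict[Category, FrameStack]:
    """Render frame stacks for the requested categories.

    The phantom applies only to the sample category; dark, bright and
    reference frames never see it. With ``cfg.noise`` off, the expectation
    image (gain · photons · signal + offset) is returned exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    gain = cfg.gain_map()
    if gain.shape != cfg.shape:
        raise ValueError("gain map shape does not match configured frame shape")
    out: dict[Category, FrameStack] = {}
    for cat_name in categories:
        cat = Category(cat_name)
        signal = _ideal_signal(cat, mask, phantom, cfg.shape)
        expected_counts = gain * cfg.photons * signal
        frames = []
        for i in range(cfg.n_frames):
            if cfg.noise:
                counts = rng.poisson(expected_counts).astype(np.float64)
                counts += cfg.dark_offset
                counts += rng.normal(0.0, cfg.read_noise, size=cfg.shape)
                counts = np.clip(counts, 0.0, None)
            else:
                counts = expected_counts + cfg.dark_offset
            frames.append(Frame(counts, cat, index=i))
        out[cat] = FrameStack(frames)
    return out


@dataclass
class PhantomVolume:
    """3-D ground-truth volumes (z, y, x); y is the beam direction at 0°."""

    mu: np.ndarray
    shift_x: np.ndarray | None = None
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=np.float64)
        if self.mu.ndim != 3:
            raise ValueError("phantom volume must be 3-D (z, y, x)")
        if self.mu.shape[1] != self.mu.shape[2]:
            raise ValueError("phantom volume cross-section must be square")
        if not np.any(self.mu != 0):
            raise ValueError("degenerate phantom volume: all zeros")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mu.shape  # type: ignore[return-value]


def cylinder_volume(
    nz: int, n: int, radius: float | None = None, mu: float = 0.01,
    center: tuple[float, float] | None = None,
) -> PhantomVolume:
    """Homogeneous cylinder along z with absorption coefficient ``mu`` per px."""
    if radius is None:
        radius = n * 0.3
    if center is None:
        center = ((n - 1) / 2.0, (n - 1) / 2.0)
    yy, xx = np.mgrid[:n, :n]
    disk = ((yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2) * mu
    return PhantomVolume(np.broadcast_to(disk, (nz, n, n)).copy())


def project_volume(volume: np.ndarray, angle_deg: float) -> np.ndarray:
    """Parallel line integral of a (z, y, x) volume at one rotation angle.

    The volume is rotated in the (y, x) plane and summed along y, in units of
    voxels (so a cylinder of coefficient µ per voxel projects to µ times the
    chord length in voxels).
    """
    if angle_deg == 0.0:
        rot = volume
    else:
        rot = ndimage.rotate(
            volume, angle_deg, axes=(1, 2), reshape=False, order=1, mode="constant"
        )
    return rot.sum(axis=1)


def _cone_distort(proj: np.ndarray, geom: Geometry) -> np.ndarray:
    """Forward cone-beam coordinate distortion (inverse of the rebin map)."""
    rows, cols = proj.shape
    p_cm = geom.pixel_um * 1e-4
    dsd = geom.dsd
    cr, cc = (rows - 1) / 2.0, (cols - 1) / 2.0
    u = (np.arange(cols) - cc) * p_cm
    v = (np.arange(rows) - cr) * p_cm
    vv, uu = np.meshgrid(v, u, indexing="ij")
    r = np.sqrt(dsd * dsd + uu * uu + vv * vv)
    t_c = uu * dsd / r / p_cm + cc
    t_r = vv * dsd / r / p_cm + cr
    return ndimage.map_coordinates(proj, np.stack([t_r, t_c]), order=1, mode="nearest")


def simulate_ct(
    volume: PhantomVolume,
    n_angles: int,
    mask: MaskSpec,
    cfg: SimConfig,
    root: str | Path,
    cone: bool = False,
) -> ProjectLayout:
    """Write a full synthetic CT project (frames on disk) for a phantom volume.

    For each of ``n_angles`` evenly spaced angles in [0°, 180°) the volume is
    rotated, line-integrated into per-angle ground-truth maps, and rendered
    into sample frames; dark, bright and reference stacks are shared across
    angles (the mask does not move during a scan). With ``cone=True`` the
    per-angle maps additionally receive the forward cone-beam coordinate
    distortion, exercising the rebinning path.
    """
    if n_angles < 2:
        raise ValueError("a CT scan needs at least 2 angles")
    nz, _, n = volume.shape
    shape = (nz, n)
    cfg = replace(cfg, shape=shape)
    layout = init_project(root, mode="ct")
    layout.write_scan_meta(n_angles)
    statics = render_frames(mask, None, cfg, categories=("dark", "bright", "reference"))
    for cat, stack in statics.items():
        for i, frame in enumerate(stack):
            save_frame(frame, layout.category_dir(cat) / frame_filename(i))
    gt_dir = layout.root / "ground_truth"
    for i in range(n_angles):
        angle = 180.0 * i / n_angles
        mu_map = project_volume(volume.mu, angle)
        shift_map = (
            project_volume(volume.shift_x, angle)
            if volume.shift_x is not None
            else np.zeros(shape)
        )
        sigma_map = (
            project_volume(volume.sigma, angle)
            if volume.sigma is not None
            else np.zeros(shape)
        )
        if cone and cfg.geometry is not None:
            mu_map = _cone_distort(mu_map, cfg.geometry)
            shift_map = _cone_distort(shift_map, cfg.geometry)
            sigma_map = _cone_distort(sigma_map, cfg.geometry)
        phantom = PhantomSpec(mu_map, shift_map, np.zeros(shape), sigma_map)
        frames = render_frames(
            mask, phantom, replace(cfg, seed=cfg.seed + 1 + i), categories=("sample",)
        )[Category.SAMPLE]
        adir = layout.angle_dir(Category.SAMPLE, i)
        for j, frame in enumerate(frames):
            save_frame(frame, adir / frame_filename(j))
        save_map(mu_map, gt_dir / f"mu_d_{i:05d}.tif")
    return layout
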