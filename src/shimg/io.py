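"""Project directory layout and TIFF I/O.

A measurement lives in a *project* directory with one subdirectory per frame
category plus an ``out/`` tree for processed products. CT projects add a
per-harmonic output tree so that each (angle, harmonic, contrast) image has a
deterministic path, which is what downstream sinogram assembly relies on.

Raw frames are stored as single-page grayscale TIFF, 16-bit unsigned;
processed maps as 32-bit float TIFF. All arithmetic elsewhere happens in
float64 regardless of storage type.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import tifffile
import yaml

from .datamodel import Category, Frame, FrameStack

__all__ = [
    "ProjectLayout",
    "init_project",
    "load_stack",
    "save_frame",
    "save_map",
    "load_map",
    "save_stack",
    "frame_filename",
    "angle_dirname",
    "load_config",
]

HARMONIC_LABELS: tuple[tuple[int, int], ...] = tuple(
    (m, n) for m in (-1, 0, 1) for n in (-1, 0, 1)
)

_ANGLE_RE = re.compile(r"angle_(\d{5})")


def frame_filename(index: int) -> str:
    return f"frame_{index:05d}.tif"


def angle_dirname(index: int) -> str:
    return f"angle_{index:05d}"


def harmonic_dirname(label: tuple[int, int]) -> str:
    m, n = label
    return f"harmonic_{m:+d}{n:+d}"


@dataclass(frozen=True)
class ProjectLayout:
    """Resolved directory layout of a measurement project."""

    root: Path
    mode: str  # "projection" | "ct"

    @property
    def out(self) -> Path:
        return self.root / "out"

    def category_dir(self, category: Category | str) -> Path:
        return self.root / Category(category).value

    def angle_dir(self, category: Category | str, angle_index: int) -> Path:
        """Per-angle frame directory (CT mode, normally the sample category)."""
        return self.category_dir(category) / angle_dirname(angle_index)

    def harmonic_dir(self, label: tuple[int, int]) -> Path:
        return self.out / harmonic_dirname(label)

    def contrast_dir(self, label: tuple[int, int], kind: str) -> Path:
        return self.harmonic_dir(label) / kind

    def ct_output_path(
        self, angle_index: int, label: tuple[int, int], kind: str
    ) -> Path:
        """Pure function of (angle, harmonic label, contrast kind)."""
        return self.contrast_dir(label, kind) / f"{angle_dirname(angle_index)}.tif"

    @property
    def scan_meta_path(self) -> Path:
        return self.out / "scan.json"

    def write_scan_meta(self, n_angles: int, angle_span_deg: float = 180.0) -> None:
        self.out.mkdir(parents=True, exist_ok=True)
        self.scan_meta_path.write_text(
            json.dumps({"n_angles": int(n_angles), "angle_span_deg": angle_span_deg})
        )

    def read_scan_meta(self) -> dict:
        return json.loads(self.scan_meta_path.read_text())


def init_project(root: str | Path, mode: str = "projection") -> ProjectLayout:
    """Create (idempotently) the project directory tree.

    ``projection`` mode: dark/, bright/, reference/, sample/, out/.
    ``ct`` mode additionally creates out/harmonic_{label}/ for the nine
    harmonics so every (angle, harmonic, contrast) product has a home.
    """
    if mode not in ("projection", "ct"):
        raise ValueError(f"unknown project mode {mode!r}")
    root = Path(root)
    try:
        root.mkdir(parents=True, exist_ok=True)
    except PermissionError:
        raise
    layout = ProjectLayout(root=root, mode=mode)
    for cat in Category:
        layout.category_dir(cat).mkdir(exist_ok=True)
    layout.out.mkdir(exist_ok=True)
    if mode == "ct":
        for label in HARMONIC_LABELS:
            layout.harmonic_dir(label).mkdir(exist_ok=True)
    return layout


def save_frame(frame: Frame, path: str | Path) -> Path:
    """Write a raw frame as 16-bit unsigned TIFF (values clipped to range)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.clip(np.rint(frame.pixels), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(path, data.astype(np.uint16))
    return path


def save_map(values: np.ndarray, path: str | Path) -> Path:
    """Write a processed map as 32-bit float TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(values, dtype=np.float32))
    return path


def load_map(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=np.float64)


def save_stack(stack: FrameStack, directory: str | Path) -> list[Path]:
    directory = Path(directory)
    paths = []
    for i, frame in enumerate(stack):
        paths.append(save_frame(frame, directory / frame_filename(i)))
    return paths


def load_stack(
    directory: str | Path,
    category: Category | str,
    angle_deg: float | None = None,
) -> FrameStack:
    """Load all TIFFs in a directory, sorted lexicographically by filename.

    16-bit (or any integer) data are promoted to float64. All frames must
    share one shape; the first offender is named in the error.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.glob("*.tif*") if p.is_file())
    if not files:
        raise FileNotFoundError(f"no TIFF files found in {directory}")
    cat = Category(category)
    frames: list[Frame] = []
    shape: tuple[int, int] | None = None
    for i, path in enumerate(files):
        px = np.asarray(tifffile.imread(str(path)), dtype=np.float64)
        if shape is None:
            shape = px.shape  # type: ignore[assignment]
        elif px.shape != shape:
            raise ValueError(
                f"frame shape mismatch: {path.name} has {px.shape}, expected {shape}"
            )
        frames.append(Frame(px, cat, angle_deg=angle_deg, index=i))
    return FrameStack(frames)


def list_angle_indices(paths: Iterable[Path]) -> list[int]:
    """Extract sorted angle indices encoded as ``angle_#####`` in names."""
    idx = []
    for p in paths:
        m = _ANGLE_RE.search(p.name)
        if m:
            idx.append(int(m.group(1)))
    return sorted(idx)


def load_config(path: str | Path) -> Mapping:
    """Read a YAML configuration (geometry / roi / processing blocks)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
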