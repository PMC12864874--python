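"""End-to-end processing: frames in, contrast maps out.

Chains the standard workflow: corrupted-frame screening → stack averaging →
ROI crop → flat-field correction → Fourier transform → harmonic detection on
the reference (once) → harmonic extraction of reference and sample →
reference correction → absorption / dark-field / differential-phase maps.
For CT projects the same chain runs per angle, reusing the harmonic
metadata measured on the shared reference, and writes every
(angle, harmonic, contrast) image into the project's output tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from . import contrast as _contrast
from .contrast import ContrastSet, retrieve_contrasts
from .datamodel import Category, Frame, FrameStack, average_stack
from .harmonics import (
    HarmonicMetadata,
    apply_metadata,
    detect_peaks,
    forward_spectrum,
)
from .io import ProjectLayout, list_angle_indices, load_stack, save_map
from .preprocess import ROI, CorrectedFrame, crop, flat_field, screen_corrupted

__all__ = ["ProcessingOptions", "correct_frames", "process_frames", "process_ct_project"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProcessingOptions:
    roi: ROI | None = None
    expected_period_px: float | None = None
    guard: float = _contrast.DEFAULT_GUARD
    unwrap_method: str = "none"
    screen_threshold: float | None = None
    export_intermediate: bool = True


def _prepare(stack: FrameStack, opts: ProcessingOptions) -> Frame:
    if opts.screen_threshold is not None and len(stack) > 1:
        stack, rejected = screen_corrupted(stack, opts.screen_threshold)
        if rejected:
            logger.info("screened out corrupted frames: %s", rejected)
    frame = average_stack(stack)
    if opts.roi is not None:
        frame = crop(frame, opts.roi)
    return frame


def correct_frames(
    dark: FrameStack,
    bright: FrameStack,
    reference: FrameStack,
    sample: FrameStack,
    opts: ProcessingOptions = ProcessingOptions(),
) -> tuple[CorrectedFrame, CorrectedFrame]:
    """Average, crop and flat-field the reference and sample stacks."""
    dark_f = _prepare(dark, opts)
    bright_f = _prepare(bright, opts)
    ref_f = _prepare(reference, opts)
    sample_f = _prepare(sample, opts)
    ref_c = flat_field(ref_f, dark_f, bright_f)
    sample_c = flat_field(sample_f, dark_f, bright_f)
    return ref_c, sample_c


def process_frames(
    dark: FrameStack,
    bright: FrameStack,
    reference: FrameStack,
    sample: FrameStack,
    opts: ProcessingOptions = ProcessingOptions(),
    meta: HarmonicMetadata | None = None,
) -> tuple[ContrastSet, HarmonicMetadata]:
    """Run the full retrieval on in-memory stacks.

    If ``meta`` is given, harmonic detection is skipped and the stored peak
    lattice is reused (the CT path, and repeat exposures generally).
    """
    ref_c, sample_c = correct_frames(dark, bright, reference, sample, opts)
    ref_spec = forward_spectrum(ref_c)
    if meta is None:
        meta = detect_peaks(ref_spec, expected_period_px=opts.expected_period_px)
    ref_h = apply_metadata(ref_spec, meta)
    sample_h = apply_metadata(forward_spectrum(sample_c), meta)
    contrasts = retrieve_contrasts(
        sample_h, ref_h, guard=opts.guard, unwrap_method=opts.unwrap_method
    )
    return contrasts, meta


def _export_contrasts(
    layout: ProjectLayout, angle_index: int, contrasts: ContrastSet
) -> None:
    save_map(
        contrasts.absorption, layout.ct_output_path(angle_index, (0, 0), "absorption")
    )
    for label, s_map in contrasts.scattering.items():
        save_map(s_map, layout.ct_output_path(angle_index, label, "scattering"))
    for label, p_map in contrasts.phase.items():
        save_map(p_map, layout.ct_output_path(angle_index, label, "dpc"))


def process_ct_project(
    layout: ProjectLayout,
    opts: ProcessingOptions = ProcessingOptions(),
) -> HarmonicMetadata:
    """Process every angle of a CT project into per-harmonic contrast images.

    Harmonic metadata is measured once on the shared reference stack, saved
    to ``out/harmonics.json``, and applied to every angle; outputs land at
    ``out/harmonic_{m}{n}/{kind}/angle_#####.tif``.
    """
    dark = load_stack(layout.category_dir(Category.DARK), Category.DARK)
    bright = load_stack(layout.category_dir(Category.BRIGHT), Category.BRIGHT)
    reference = load_stack(layout.category_dir(Category.REFERENCE), Category.REFERENCE)

    sample_root = layout.category_dir(Category.SAMPLE)
    angle_dirs = sorted(d for d in sample_root.glob("angle_*") if d.is_dir())
    if not angle_dirs:
        raise FileNotFoundError(f"no per-angle sample directories in {sample_root}")
    indices = list_angle_indices(angle_dirs)
    meta_scan = layout.read_scan_meta() if layout.scan_meta_path.exists() else {}
    n_angles = int(meta_scan.get("n_angles", len(indices)))
    span = float(meta_scan.get("angle_span_deg", 180.0))

    meta: HarmonicMetadata | None = None
    for i, adir in zip(indices, angle_dirs):
        sample = load_stack(adir, Category.SAMPLE, angle_deg=i * span / n_angles)
        contrasts, meta = process_frames(dark, bright, reference, sample, opts, meta)
        _export_contrasts(layout, i, contrasts)
    assert meta is not None
    meta.save(layout.out / "harmonics.json")
    return meta
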