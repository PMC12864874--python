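import numpy as np
import pytest

from shimg import (
    Category,
    MaskSpec,
    PhantomSpec,
    SimConfig,
    disk_phantom,
    render_frames,
)
from shimg.pipeline import ProcessingOptions, process_frames

SHAPE = (256, 256)
PERIOD = 8.0


@pytest.fixture
def mask() -> MaskSpec:
    return MaskSpec(period=PERIOD)


@pytest.fixture
def noiseless_cfg() -> SimConfig:
    return SimConfig(shape=SHAPE, photons=1e4, noise=False, seed=7)


@pytest.fixture
def noisy_cfg() -> SimConfig:
    return SimConfig(shape=SHAPE, photons=1e4, noise=True, seed=7)


def run_pipeline(mask, phantom, cfg, opts: ProcessingOptions | None = None):
    """Simulate four categories and run full retrieval; returns (contrasts, meta)."""
    stacks = render_frames(mask, phantom, cfg)
    return process_frames(
        stacks[Category.DARK],
        stacks[Category.BRIGHT],
        stacks[Category.REFERENCE],
        stacks[Category.SAMPLE],
        opts or ProcessingOptions(),
    )


def interior_disk_mask(map_shape, frame_shape, radius, margin=4.0):
    """Boolean mask of the disk interior, rescaled to harmonic-map coordinates."""
    L0, L1 = map_shape
    scale = L0 / frame_shape[0]
    yy, xx = np.mgrid[:L0, :L1]
    c0, c1 = (L0 - 1) / 2.0, (L1 - 1) / 2.0
    r = np.hypot(yy - c0, xx - c1)
    return r < radius * scale - margin


@pytest.fixture
def absorber_disk() -> PhantomSpec:
    return disk_phantom(SHAPE, radius=70, mu_d=0.7)
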