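import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from shimg import (
    Category,
    MaskSpec,
    PhantomSpec,
    SimConfig,
    absorption,
    combine_directions,
    disk_phantom,
    dpc,
    reference_correct,
    render_frames,
    render_mask,
    scattering,
    unwrap,
)
from shimg.contrast import available_unwrap_methods
from shimg.harmonics import HarmonicImage
from shimg.pipeline import process_frames

from conftest import PERIOD, SHAPE, interior_disk_mask, run_pipeline


def himage(label, values):
    return HarmonicImage(label, np.asarray(values, dtype=complex))


def const_h(label, value, shape=(32, 32)):
    return himage(label, np.full(shape, value, dtype=complex))


class TestReferenceCorrect:
    def test_identity_and_scaling_and_phase(self):
        ref = const_h((1, 0), 0.4 + 0.1j)
        assert np.allclose(reference_correct(ref, ref).values, 1.0)
        half = himage((1, 0), ref.values * 0.5)
        assert np.allclose(reference_correct(half, ref).values, 0.5)
        rot = himage((1, 0), ref.values * np.exp(1j * np.pi / 3))
        out = reference_correct(rot, ref)
        assert np.allclose(np.abs(out.values), 1.0)
        assert np.allclose(np.angle(out.values), np.pi / 3)

    def test_label_mismatch_prevents_cross_harmonic_division(self):
        with pytest.raises(ValueError, match="label"):
            reference_correct(const_h((1, 0), 1.0), const_h((0, 1), 1.0))

    def test_weak_reference_pixels_masked(self):
        ref_vals = np.full((32, 32), 1.0 + 0j)
        ref_vals[4, 4] = 1e-9
        out = reference_correct(const_h((0, 0), 1.0), himage((0, 0), ref_vals))
        assert not out.valid[4, 4]
        assert np.all(np.isfinite(out.values.real))


class TestAbsorption:
    def test_unity_ratio_gives_zero_and_ln_inverse(self):
        ratio = reference_correct(const_h((0, 0), 1.0), const_h((0, 0), 1.0))
        assert np.allclose(absorption(ratio), 0.0)
        ratio_e = reference_correct(const_h((0, 0), np.exp(-1.0)), const_h((0, 0), 1.0))
        assert np.allclose(absorption(ratio_e), 1.0)

    def test_requires_fundamental_label(self):
        ratio = reference_correct(const_h((0, 1), 1.0), const_h((0, 1), 1.0))
        with pytest.raises(ValueError):
            absorption(ratio)

    def test_recovers_optical_thickness_of_simulated_disk(
        self, mask, noiseless_cfg, absorber_disk
    ):
        contrasts, _ = run_pipeline(mask, absorber_disk, noiseless_cfg)
        interior = interior_disk_mask(contrasts.absorption.shape, SHAPE, 70)
        assert contrasts.absorption[interior].mean() == pytest.approx(0.7, rel=0.02)


class TestScattering:
    def test_zero_for_identical_sample_and_reference(self, mask, noiseless_cfg):
        contrasts, _ = run_pipeline(mask, PhantomSpec.null(SHAPE), noiseless_cfg)
        for s_map in contrasts.scattering.values():
            assert np.max(np.abs(s_map)) < 1e-8

    def test_pure_absorber_cancels(self, mask, noiseless_cfg, absorber_disk):
        contrasts, _ = run_pipeline(mask, absorber_disk, noiseless_cfg)
        # stay away from the disk edge: band-limiting rings there
        interior = interior_disk_mask(contrasts.absorption.shape, SHAPE, 70, margin=6)
        for label in ((0, 1), (1, 0)):
            s = contrasts.scattering[label][interior]
            assert np.abs(s).mean() < 5e-3
            assert np.abs(s).max() < 0.02

    def test_fundamental_label_rejected(self):
        ratio = reference_correct(const_h((0, 0), 1.0), const_h((0, 0), 1.0))
        with pytest.raises(ValueError):
            scattering(ratio, const_h((0, 0), 1.0), const_h((0, 0), 1.0))

    def test_diffuser_matches_numeric_convolution_oracle(self, mask, noiseless_cfg):
        """Mean S in a Gaussian diffuser vs direct convolution of the pattern."""
        sigma = 1.0
        phantom = disk_phantom(SHAPE, radius=70, mu_d=0.0, sigma=sigma)
        contrasts, _ = run_pipeline(mask, phantom, noiseless_cfg)
        interior = interior_disk_mask(contrasts.absorption.shape, SHAPE, 70)
        measured = contrasts.scattering[(0, 1)][interior].mean()

        # oracle: blur the bare pattern, project both onto the first-harmonic
        # carrier and compare amplitudes
        pattern = render_mask(mask, SHAPE)
        blurred = gaussian_filter(pattern, sigma, mode="wrap")
        carrier = np.exp(-2j * np.pi * np.arange(SHAPE[1]) / PERIOD)[None, :]
        a_ref = np.abs((pattern * carrier).mean())
        a_blur = np.abs((blurred * carrier).mean())
        oracle = -np.log(a_blur / a_ref)
        assert measured == pytest.approx(oracle, rel=0.02)
        assert measured == pytest.approx(2 * np.pi**2 * sigma**2 / PERIOD**2, rel=0.10)

    def test_monotone_in_sigma(self, mask, noiseless_cfg):
        means = []
        for sigma in (0.6, 0.8, 1.0, 1.2, 1.4):
            phantom = disk_phantom(SHAPE, radius=70, mu_d=0.0, sigma=sigma)
            contrasts, _ = run_pipeline(mask, phantom, noiseless_cfg)
            interior = interior_disk_mask(contrasts.absorption.shape, SHAPE, 70)
            means.append(contrasts.scattering[(0, 1)][interior].mean())
        assert all(b > a for a, b in zip(means, means[1:]))


class TestDpc:
    def test_zero_for_identical_sample(self, mask, noiseless_cfg):
        contrasts, _ = run_pipeline(mask, PhantomSpec.null(SHAPE), noiseless_cfg)
        for p_map in contrasts.phase.values():
            assert np.max(np.abs(p_map)) < 1e-8

    def test_quarter_period_shift_gives_half_pi(self, mask, noiseless_cfg):
        phantom = PhantomSpec.null(SHAPE)
        phantom.shift_x += PERIOD / 4
        contrasts, _ = run_pipeline(mask, phantom, noiseless_cfg)
        p_plus = contrasts.phase[(0, 1)]
        p_minus = contrasts.phase[(0, -1)]
        assert np.allclose(np.abs(p_plus), np.pi / 2, atol=1e-3)
        assert np.allclose(p_minus, -p_plus, atol=1e-3)

    def test_directional_selectivity(self, mask, noiseless_cfg):
        """x-only displacement moves only the x-direction harmonics."""
        phantom = PhantomSpec.null(SHAPE)
        phantom.shift_x += PERIOD / 4
        contrasts, _ = run_pipeline(mask, phantom, noiseless_cfg)
        along = np.abs(contrasts.phase[(0, 1)]).mean()
        across = np.abs(contrasts.phase[(1, 0)]).mean()
        assert across < 0.05 * along

    def test_fundamental_label_rejected(self):
        ratio = reference_correct(const_h((0, 0), 1.0), const_h((0, 0), 1.0))
        with pytest.raises(ValueError):
            dpc(ratio)

    def test_antisymmetry_between_conjugate_labels(self, mask, noiseless_cfg):
        phantom = disk_phantom(SHAPE, radius=70, mu_d=0.2, shift=(0.0, 1.0))
        contrasts, _ = run_pipeline(mask, phantom, noiseless_cfg)
        for m, n in ((0, 1), (1, 0), (1, 1)):
            assert np.allclose(
                contrasts.phase[(m, n)], -contrasts.phase[(-m, -n)], atol=1e-6
            )


class TestExposureInvariance:
    def test_global_sample_exposure_shifts_a_only(self, mask, noiseless_cfg):
        phantom = disk_phantom(SHAPE, radius=70, mu_d=0.3, sigma=0.8)
        stacks = render_frames(mask, phantom, noiseless_cfg)
        args = [
            stacks[Category.DARK],
            stacks[Category.BRIGHT],
            stacks[Category.REFERENCE],
            stacks[Category.SAMPLE],
        ]
        base, _ = process_frames(*args)
        c = 0.8
        dark = stacks[Category.DARK][0].pixels
        scaled_sample = [
            f.with_pixels(dark + c * (f.pixels - dark)) for f in stacks[Category.SAMPLE]
        ]
        from shimg.datamodel import FrameStack

        args[3] = FrameStack(scaled_sample)
        scaled, _ = process_frames(*args)
        assert np.allclose(scaled.absorption - base.absorption, -np.log(c), atol=1e-6)
        for label in base.scattering:
            assert np.allclose(scaled.scattering[label], base.scattering[label], atol=1e-6)
            assert np.allclose(scaled.phase[label], base.phase[label], atol=1e-6)


class TestCombineAndUnwrap:
    def test_combine_directions_arithmetic(self):
        a = np.zeros((8, 8))
        b = np.full((8, 8), np.pi / 2)
        assert np.allclose(combine_directions(a, b), np.pi / 4)
        assert np.allclose(combine_directions(b, b), b)
        assert np.allclose(combine_directions(b, -b), 0.0)
        with pytest.raises(ValueError):
            combine_directions(a, np.zeros((8, 9)))

    def test_smooth_map_unchanged_and_none_is_identity(self):
        p = np.linspace(-2, 2, 64).reshape(8, 8) * 0.5
        assert np.allclose(unwrap(p, "quality"), p, atol=1e-12)
        assert np.array_equal(unwrap(p, "none"), p)

    def test_wrapped_ramp_restored_against_cumulative_oracle(self):
        true_ramp = np.tile(np.linspace(0, 6 * np.pi, 128), (16, 1))
        wrapped = np.angle(np.exp(1j * true_ramp))
        out = unwrap(wrapped, "quality")
        # cumulative-difference oracle along a row
        row = wrapped[0]
        oracle = row.copy()
        correction = 0.0
        for i in range(1, len(row)):
            d = row[i] - row[i - 1]
            if d > np.pi:
                correction -= 2 * np.pi
            elif d < -np.pi:
                correction += 2 * np.pi
            oracle[i] = row[i] + correction
        out_row = out[0] - out[0, 0] + oracle[0]
        assert np.allclose(out_row, oracle, atol=1e-9)
        # congruence modulo 2pi
        assert np.allclose(np.angle(np.exp(1j * (out - wrapped))), 0.0, atol=1e-9)

    def test_unknown_method_lists_available(self):
        with pytest.raises(ValueError, match="none"):
            unwrap(np.zeros((8, 8)), "magic")
        assert {"none", "quality"} <= set(available_unwrap_methods())
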