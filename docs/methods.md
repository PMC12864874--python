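# Methods

## The measurement model

Spatial harmonic imaging places a periodic absorbing mesh (an inverted
Hartmann mask: metal pillars on a transparent substrate) in an X-ray beam.
The detector records the mesh's intensity pattern; a sample placed in the
beam modifies that pattern in three independent ways, each read out from a
different property of the pattern's Fourier harmonics:

* **attenuation** scales the whole pattern (Beer–Lambert, `exp(-µ·d)`);
* **refraction** displaces the beamlets laterally, i.e. translates the
  pattern locally;
* **sub-pixel small-angle scattering** blurs the pattern locally, reducing
  its modulation depth (visibility) without changing its mean.

Because the mask is periodic with projected period `d` (detector pixels),
the 2-D Fourier transform of a frame is a lattice of harmonic peaks at
multiples of the fundamental frequency `1/d`. Each harmonic image — the
inverse transform of a band-limited window cut around one peak — factorizes
as

    I_{m,n}(x, y) = I_0(x, y) · D_{m,n}(x, y) · exp(i ψ_{m,n}(x, y)),

with `I_0` the transmitted intensity, `D` the visibility amplitude and `ψ`
the displacement phase. Dividing each sample harmonic by the matching
reference (mask-only) harmonic cancels the mask and illumination factors.
The contrast maps are then

    A      = -ln |I^S_00 / I^R_00|                       (absorption, µ·d)
    S_mn   = -ln [ (|I^S_mn|/|I^S_00|) / (|I^R_mn|/|I^R_00|) ]   (dark-field)
    P_mn   = arg (I^S_mn / I^R_mn)  ∈ (-π, π]             (differential phase)

at first order (0,±1), (±1,0) and, with the same formulas, at the diagonal
(±1,±1) channels. `P = 2πδ/d` for a rigid pattern displacement `δ` along the
harmonic direction; for a Gaussian diffuser of width σ (pixels),
`S = 2π²σ²/d²` exactly, because a Gaussian blur multiplies the fundamental
Fourier component by `exp(-2π²σ²/d²)` while leaving the mean unchanged.
Label convention: `(m, n)` indexes (row, column) spatial frequency; `(0, ±1)`
are therefore the horizontal (x-direction) channels.

## Processing pipeline and its numerical choices

1. **Screening and averaging.** Frames whose mean deviates from the stack's
   median-of-means by more than a relative threshold (default off; 0.5 is a
   reasonable setting) are dropped. Stacks are averaged in float64. The
   `rmse_convergence` diagnostic reports the RMSE between the cumulative
   mean of the first *n* frames and the full mean; its last point is exactly
   zero and its first point is ≈ σ·√(1−1/N) for i.i.d. noise.
2. **Flat-field.** `(I − D)/(B − D)`, mapping the bright level to 1. The
   denominator guard is `1e-6 · max(B)` (scale-invariant); guarded and
   saturated (16-bit ceiling) pixels are flagged in a validity mask and set
   to 0 rather than NaN so the FFT stays finite.
3. **Harmonic detection** runs once on a reference spectrum (centered
   convention, zero frequency at `(rows//2, cols//2)`). Without a period
   hint, the strongest non-DC peak in a half-plane gives one lattice vector
   and the strongest non-collinear peak the other; with a hint, the search
   starts from the predicted bins. All nine `(m,n) ∈ {−1,0,1}²` positions
   are then snapped to the local magnitude maximum within ±2 bins,
   compensating residual displacements from source size, sampling and mask
   tilt. Peak centers are integer bins — sub-bin drift becomes a common
   linear phase ramp that the reference division cancels. The band limit is
   `floor(spacing/2)`, placing the window edge at the midpoint between
   neighboring harmonics; the same limit is used for every harmonic so all
   harmonic images share one shape, `(2·band_limit+1)²`. A projected period
   below 3 px violates the sampling limit and is rejected
   (`NyquistError`); peaks below `1e-3` of the DC magnitude raise
   `MaskNotResolvedError` (the noise-floor ratio is configurable).
4. **Extraction and reference correction.** Windows are re-centered onto
   zero frequency and inverse-transformed (no apodization by default).
   Ratios are masked where the reference harmonic modulus falls below a
   guard (default `1e-3` of its maximum). Masked pixels are excluded, not
   clipped.
5. **Phase unwrapping** is a pluggable registry: `none` (default — the
   retrieval itself needs no unwrapping) and `quality`
   (reliability-sorted 2-D unwrapping); users can register more.
6. **Bidirectional maps** are the plain arithmetic mean of the horizontal
   and vertical maps.

## CT preparation and reconstruction

With the mask at distance `D1` from the source and the sample at `D2`
(`D1 ≤ D2 < Dsd`), the mask period projected onto the sample plane grows by
`D2/D1`; the *mask-limited effective pixel* is therefore
`p_eff = p_detector·D2/D1` (51.7 µm at the 49.5 µm / 68 cm / 71 cm operating
point), while the plain geometric sample-plane pixel is `p_detector·D2/Dsd`
(≈ 11 µm at Dsd = 318 cm). Because each harmonic is band-limited at `1/d`,
cone-beam magnification differences below that scale are suppressed and the
system may be treated as parallel-beam for reconstruction.

Optionally, projections are rebinned: detector coordinate `(u, v)` maps to
parallel-ray coordinate `t = u·Dsd/√(Dsd²+u²+v²)` (pixel units; identity as
`Dsd → ∞`), resampled bilinearly on the regular output grid via the closed-form
inverse `s = q·Dsd/√(Dsd²−q²)` of the radial map. At laboratory distances the
residual between raw and rebinned unit-normalized projections has MSE well
below 1e-4 on a 512-px detector. The rebinned array carries a provenance
marker and a second rebin raises — the map must not be applied twice.

Reconstruction is classical parallel-beam filtered backprojection with the
Ram-Lak (ramp) filter; only the rotation center is user-specified (the
sinogram is shifted to put the axis at the backprojector's expected
position). Quality metrics against a reference reconstruction:
NRMSE = RMSE/(max−min of reference); PSNR = 10·log₁₀(range²/MSE) with +∞
for an exact match; MSSIM with a 7×7 window (shrunk, odd, on images smaller
than 7) and constants on the reference range; NMI = (H(X)+H(Y))/H(X,Y) with
256-bin histograms, lying in [1, 2]. The projection-count study decimates
angles to evenly spaced subsets that always include angle 0.

## The synthetic forward model

The simulator emulates the four acquisition categories. Sample formation
order: warp the mask pattern by the displacement field (bilinear, periodic
boundary), multiply by `exp(−µ·d)`, blur with a per-region Gaussian
(piecewise-constant σ keeps the cost at one convolution per distinct σ),
then multiply by a smooth flat-field gain map (±5% cosine structure),
scale to the photon level, apply Poisson noise, add the dark offset
(100 ADU) and Gaussian read noise (2 ADU). Defaults: 512×512 frames with
a period-8 mask — a desk-scale stand-in for a 5690×4608 detector at
d ≈ 4.7 px — duty 0.5, pillar transmission 0.05, 10⁴ photons/pixel, one
frame per category (the retrieval works single-shot; tests that probe
averaging use 100). All randomness flows from one seed; identical
configurations produce byte-identical TIFFs.

CT scans rotate a (z, y, x) phantom volume in the (y, x) plane
(bilinear, no reshape) and sum along y, giving per-angle optical-thickness
maps in units of 1/voxel; an optional cone mode applies the forward
divergent-beam coordinate distortion so the rebinning path can be
exercised. Because the harmonic maps are `(2b+1)` pixels wide for an
`n`-pixel frame, a reconstructed attenuation coefficient is in units of the
coarse pixel; multiply by `(2b+1)/n` to compare with the per-fine-pixel
ground truth.

What the simulator does *not* model: Fresnel propagation and wave-optical
edge fringes, polychromatic spectra and beam hardening, detector PSF and
charge sharing, source-size penumbra beyond what the Gaussian blur absorbs,
and scatter that varies within one phantom region. Passing tests therefore
demonstrate the correctness of the retrieval algebra, the harmonic
bookkeeping and the CT plumbing — not robustness to those physical effects.

## Test problem sizes

Unit and property tests run on 256² frames (CT: 96² frames, 60–180 angles,
period-4 mask for finer harmonic sampling); the noiseless-limit recovery
targets are µ·d within 2%, rigid-shift phase within 10⁻³ rad, and diffuser
dark-field within 10% of 2π²σ²/d² over σ ∈ {0.6 … 1.4} px (below σ ≈ 0.5 px
the discrete Gaussian kernel departs from its continuum transfer function,
so the grid starts at 0.6). The acceptance script (`scripts/acceptance.py`)
re-runs the same computations from scratch at those sizes.

## Known limitations

* Square harmonic windows tied to the *smaller* axis spacing penalize very
  non-square ROIs; prefer near-square ROIs.
* Integer-bin peak centers leave a residual linear phase ramp if the mask
  drifts between reference and sample exposures (the reference correction
  cancels only common ramps).
* `S` is unbounded where the sample destroys the pattern entirely; such
  pixels are masked by the reference-modulus guard rather than clipped.
* The rebinning map assumes a flat detector normal to the principal ray.
* Interoperability with externally produced project folders depends on the
  `frame_#####.tif` / `angle_#####` naming convention documented in `io`.
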