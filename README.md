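# shimg — spatial harmonic X-ray imaging

Single-shot multicontrast X-ray imaging for laboratory sources: a periodic
absorbing mesh (an inverted Hartmann mask) modulates the beam, and the
sample's **absorption**, **differential phase** (refraction) and
**dark-field** (sub-pixel small-angle scattering) signals are separated as
harmonics of the mesh pattern in Fourier space — from one sample exposure,
with no grating stepping. The package is aimed at people building or using
mesh-based multicontrast setups who need the full offline chain: raw frame
handling, flat-field correction, automatic harmonic bookkeeping, contrast
retrieval, CT preparation and reconstruction, plus a synthetic forward
simulator that makes every step testable without a beamline.

## The model

With a mask of projected period `d` detector pixels (`d ≥ 3`, Nyquist), each
harmonic image — the inverse transform of a band-limited window around peak
`(m, n)` of the frame's 2-D spectrum — factorizes as
`I_{m,n} = I_0 · D_{m,n} · exp(i ψ_{m,n})`. Dividing sample by reference
harmonics cancels mask and illumination, and

```
A    = -ln |I^S_00 / I^R_00|                                  (µ·d, Beer–Lambert)
S_mn = -ln [ (|I^S_mn|/|I^S_00|) / (|I^R_mn|/|I^R_00|) ]      (dark-field)
P_mn = arg (I^S_mn / I^R_mn)                                  (differential phase)
```

`P = 2πδ/d` for a beamlet displacement `δ`; a Gaussian diffuser of width σ
gives `S = 2π²σ²/d²`. See `docs/methods.md` for the full account.

## Worked example

Simulate a disk that both absorbs (µ·d = 0.7) and scatters (σ = 0.8 px)
behind a period-8 mask, 20 noisy frames per category, then run the
retrieval:

```python
import numpy as np
from shimg import MaskSpec, SimConfig, disk_phantom, render_frames, Category
from shimg.pipeline import process_frames

mask = MaskSpec(period=8.0)
cfg = SimConfig(shape=(256, 256), photons=1e4, noise=True, seed=42, n_frames=20)
phantom = disk_phantom((256, 256), radius=70, mu_d=0.7, sigma=0.8)
stacks = render_frames(mask, phantom, cfg)
contrasts, meta = process_frames(
    stacks[Category.DARK], stacks[Category.BRIGHT],
    stacks[Category.REFERENCE], stacks[Category.SAMPLE],
)
print(f"projected period : {meta.period_px:.2f} px")
print(f"band limit       : {meta.band_limit} bins")
L = contrasts.absorption.shape[0]
yy, xx = np.mgrid[:L, :L]
inside = np.hypot(yy - (L-1)/2, xx - (L-1)/2) < 70 * L / 256 - 4
print(f"A (disk interior): {contrasts.absorption[inside].mean():.4f}   (true mu*d = 0.7)")
s_bi = contrasts.bidirectional_scattering()
print(f"S (disk interior): {s_bi[inside].mean():.4f}   (theory 2*pi^2*sigma^2/d^2 = {2*np.pi**2*0.8**2/64:.4f})")
print(f"P (disk interior): {contrasts.phase[(0, 1)][inside].mean():+.4f}  (no refraction simulated)")
```

Output:

```
projected period : 8.00 px
band limit       : 16 bins
A (disk interior): 0.7023   (true mu*d = 0.7)
S (disk interior): 0.1984   (theory 2*pi^2*sigma^2/d^2 = 0.1974)
P (disk interior): -0.0001  (no refraction simulated)
```

The absorption map recovers the optical thickness within 0.4%, the
dark-field map matches the Gaussian-diffuser prediction within 1%, and the
phase map is zero because the phantom does not refract. Contrast maps have
side `2·band_limit + 1` (here 33): harmonic extraction resolves the image at
the mask-period scale, not the detector-pixel scale.

The same pipeline runs from the shell on TIFF project directories:

```
shimg simulate --phantom disk --shape 256 --out proj/
shimg process --root proj/ --period 8
shimg simulate --phantom cylinder-ct --shape 96 --period 4 --angles 90 --out ct/
shimg ct-prep --root ct/
shimg reconstruct --root ct/ --label 0,0 --kind absorption --counts 18,45,90
```

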