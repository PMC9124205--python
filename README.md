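# blindsim

Simulation and deconvolution toolkit for **blind structured-illumination
microscopy** (blind-SIM): super-resolving fluorescence images acquired under
unknown speckle illumination, where only the *statistics* of the
illumination — not the individual patterns — are available to the
reconstruction.

The package is aimed at microscopists and method developers who want a
self-contained, reproducible sandbox for speckle-based super-resolution:
every experiment here runs from a single seed, from phantom to metric, on
one CPU.

## What it does

1. **Simulate the acquisition.** A ground-truth fluorophore density
   `rho(r)` (the Siemens-star resolution target `rho = 1 + cos 20θ`, or
   synthetic cell-like scenes) is illuminated by N speckle fields `I_n`
   built from random-phase plane waves with a spatial-frequency cutoff that
   sets the grain size `d_sp`. Each product `rho · I_n` is blurred by an
   Airy-disk PSF of FWHM `d_PSF`, giving low-resolution frames `LR_n`. The
   ratio `η = d_PSF / d_sp` (benchmarks use η = 2.5) controls how much
   super-resolving information survives.
2. **Sparsify.** Each frame is reduced to its high-positive part
   `HP_n = (LR_n − mean LR)⁺`, keeping only the pixels above the pixelwise
   stack mean — the bright speckle grains.
3. **Deconvolve**, three ways:
   * **SAI** (scattering-assisted imaging): each HP frame is fit by K Airy
     atoms of size `d_sp` — `g_n = Σ_k P_nk h̃(r − r_nk)` — via stochastic
     local search on the L1 objective `F = Σ|g_n ⊛ h − HP_n|`; the
     reconstruction is the ensemble average `G = Σ_n g_n / N`.
   * **Lucy–Richardson**: the classical single-image baseline on the stack
     mean.
   * **BS-CNN**: an encoder–decoder network (3×3 convs, features
     32→512→32, 4×4 max-pools, SSIM loss, Adam) mapping each HP frame to an
     estimate of `rho · I_n`, ensemble-averaged at inference. The network,
     its SSIM loss gradient and the Adam trainer are implemented directly
     on numpy arrays and run CPU-only.
4. **Score.** Resolution is read off the Siemens star by the
   Fourier-transform contrast `FTC(R) = |c_20|/c_0` of azimuthal profiles
   (ground truth → 0.5; Rayleigh criterion at FTC = 0.08, the ring radius
   where spokes become resolved), summarized as the **resolution
   improvement** (ratio of LR to method Rayleigh radii). **Fidelity** is
   SSIM against the ground truth after unit-max normalization.

See `docs/methods.md` for conventions, parameter defaults and limitations.

## Worked example

```python
import blindsim as bs

star = bs.make_siemens_star(128)            # FOV = 13 d_PSF -> d_PSF = 9.85 px
d_psf, d_sp = star.d_psf_px, star.d_psf_px / 2.5
psf = bs.airy_psf(d_psf)

stack = bs.speckle_stack(bs.SpeckleParams(d_sp=d_sp, seed=1), 200, star.shape)
lr = bs.blur(bs.illuminate(star, stack), psf)
hp = bs.hp_extract(lr)

result = bs.sai_reconstruct(hp, d_sp, psf, seed=2, pixel_pitch=star.pixel_pitch)

radii = bs.default_ftc_radii(128, d_sp, d_psf)
lr_curve = bs.ftc_curve(lr.mean_frame(), 20, radii, center=star.center)
g_curve = bs.ftc_curve(result.reconstruction.pixels, 20, radii, center=star.center)
print("LR fidelity  ", round(bs.fidelity(lr.mean_frame(), star).value, 3))
print("SAI fidelity ", round(bs.fidelity(result.reconstruction, star).value, 3))
print("improvement  ", round(bs.resolution_improvement(g_curve, lr_curve), 2))
```

Output (seed-exact):

```
LR fidelity   0.394
SAI fidelity  0.433
improvement   1.52
```

The LR star resolves its spokes only at the radius where the local period
exceeds the diffraction limit; the SAI ensemble average pushes that radius
inward by a factor 1.5 at N = 200 (larger stacks sharpen it further) while
scoring closer to the ground truth than the blurred image itself.

The same pipeline is available from the shell:

```bash
blindsim phantom star --size 128 --out star.tif
blindsim forward --gt star.tif --dsp 3.94 --dpsf 9.85 --n 200 --seed 1 \
    --out-lr lr.tif --out-hp hp.tif
blindsim sai --hp hp.tif --dsp 3.94 --dpsf 9.85 --seed 2 --out recon.tif
blindsim evaluate --recon recon.tif --gt star.tif --lr lr.tif \
    --dsp 3.94 --dpsf 9.85 --out report.json
```

(`blindsim benchmark --config bench.cfg --out outdir` runs the whole
comparison from one config file.)

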