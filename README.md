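# blindau

Blind deconvolution in autocorrelation space for multiview light-sheet
fluorescence microscopy.

In light-sheet microscopy the point spread function (PSF) is elongated along
the detection/scan axis, so specimens are routinely imaged from several
angles and the views fused to recover isotropic resolution.  Two practical
obstacles stand in the way: the views must be registered against each other,
and the PSF — needed for deconvolution — is often not measurable (cleared
samples, fluidic systems).  `blindau` addresses both at once.  It is written
for microscopists and image-analysis developers working with multiview
acquisitions who want a deblurred, aligned reconstruction *and* an estimate
of the instrument's PSF without ever measuring beads.

## Method

Each view is modeled as `f_i = o * h_i + eps_i`.  Instead of aligning the
views, the package fuses them in shift space through the averaged
autocorrelation

    chi = (1/m) Σ_i | f_i ⋆ f_i | ,

which is invariant to the translation of every individual view.  For a
consistent measurement, `chi = (o ⋆ o) * H` with `H = h ⋆ h`, where `h` is
the average of the per-view PSFs (for orthogonal views, a star/cross-shaped
kernel).  Both unknowns are recovered from chi alone by alternating two
multiplicative Anchor-Update (AU) blocks, each structurally identical to a
Richardson–Lucy (RL) update with an effective kernel rebuilt from the
current iterate:

    object block (PSF frozen):   K = o ⋆ H,   o ← o · [(chi / (o * K)) * K~]
    PSF block (object frozen):   K' = h ⋆ O,  h ← h · [(chi / (h * K')) * K'~]

Nonnegativity is preserved by construction, total flux is conserved, and the
solution carries the intrinsic translation/reflection ambiguity of
autocorrelations (registered automatically before any comparison to ground
truth).  Classic RL deconvolution and known-PSF AU inversion are included as
free-standing solvers, along with the full preprocessing chain (dark-frame
subtraction, 90° rotations, cross-correlation registration, fusion,
zero-flooring), a synthetic vessel-phantom simulator, and MSE/SNR metrics.

## Worked example

The bundled synthetic study: a 191×191 vessel phantom is blurred by Gaussian
PSFs (σ = 2.7 px axial, 1 px lateral) at 0° and 90°, normalized to 2¹⁶, and
corrupted by Poisson noise (λ = 2⁸).  The blind solver starts from the
aligned fused average and an isotropic σ = 4 px PSF guess; an RL arm with
the exact star-shaped average PSF serves as the known-PSF reference.

```python
import blindau as ba

cfg = ba.ExperimentConfig(
    phantom=ba.PhantomSpec(seed=1),
    schedule=ba.BlindSchedule(object_inner_iters=50, psf_inner_iters=50,
                              outer_cycles=200, checkpoint_every=20),
    rl_iters=2000,
    seed=1,
)
report = ba.run_synthetic_experiment(cfg, out_dir="demo")
```

Output of this exact run (~1.5 min on one core; `demo/` receives the TIFF
rasters, metric traces, and the JSON report):

```
snr_view_db    77.37      # SNR (Eq. above) of one preprocessed measurement
snr_fused_db   77.18      # SNR of the aligned two-view average
snr_blind_db   99.47      # SNR of the blind reconstruction
snr_rld_db     80.49      # SNR of the known-PSF RL reconstruction
mse_blind      9.07e-08   # energy-normalized MSE, re-blurred blind recon vs fused
mse_rld        5.82e-11   # same for the RL arm (its noise-set convergence floor)
```

Both reconstructions sharpen the measurement (higher SNR), and the blindly
recovered kernel matches the true cross-shaped average PSF: registered
normalized cross-correlation 0.979, arm orientation within 1° — starting
from a featureless isotropic guess.

The same pipeline is scriptable from the shell:

```
blindau simulate --out sim --seed 1
blindau fuse --views sim/view_0.tif --views sim/view_1.tif --out chi.tif --guess guess.tif
blindau blind --chi chi.tif --guess guess.tif --psf-sigma 4 --cycles 200 --out recon
blindau metrics --recon recon/object_blind.tif --psf recon/psf_blind.tif --measurement guess.tif
```

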