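# Methods

`blindau` reconstructs a deblurred, intrinsically aligned image of a specimen
from a multiview light-sheet acquisition in which the point spread function
(PSF) is unknown.  This note documents the model, the algorithms, the
numerical choices, and what the synthetic studies bundled with the package do
and do not demonstrate.

## Image-formation model

Each view `i` of a light-sheet acquisition is modeled as an isoplanatic blur
plus noise,

    f_i = o * h_i + eps_i ,

where `o` is the object, `h_i` the PSF of that view (in multiview geometry
the per-view PSFs differ only by the acquisition angle), `*` denotes
convolution, and `eps_i` is detection noise.  The PSF of a light-sheet
microscope is elongated along the detection/scan axis; averaging two
orthogonal views therefore produces a star/cross-shaped effective kernel.

Rather than aligning and fusing the views in image space, the package fuses
them in *shift space*: the averaged autocorrelation

    chi = (1/m) sum_i | f_i ⋆ f_i |

is invariant to translation of every individual view (autocorrelation drops
absolute position), so no registration of any kind is needed to build it.
For a consistent measurement, chi relates to the fused object and average
PSF `h` through

    chi = (o ⋆ o) * H ,      H = h ⋆ h .

## Solvers

Three multiplicative fixed-point schemes share one algebraic structure:

* **Richardson–Lucy (RL)** inverts `f = o * h` for known `h`:
  `o <- o · [(f / (o * h)) * h~]`, with `h~` the coordinate-reversed kernel.
* **Anchor Update (AU)** inverts `chi = (o ⋆ o) * H` for known `H` by using
  an *effective kernel* rebuilt from the current iterate, `K = o ⋆ H`, in an
  RL-shaped update: `o <- o · [(chi / (o * K)) * K~]`.
* **Blind-AU** alternates AU blocks on the single input chi: `t` iterations
  updating the object with `H` frozen (recomputed from the current PSF once
  per block), then `t'` iterations updating the PSF with `O = o ⋆ o` frozen,
  repeated for `k` outer cycles.  The PSF estimate is renormalized to unit
  sum at each block boundary; the object's scale is left to be set by chi.

Properties relied on throughout (and verified by the test suite):

* nonnegativity of all iterates is preserved — every factor is nonnegative,
  so no positivity projection is ever applied;
* total flux locks onto the value implied by the data after one iteration
  (`sum(f)` for RL, `sum(chi)` for AU) and is conserved thereafter under
  cyclic boundaries;
* the update is exactly invariant to a rescaling of the kernel (it enters
  once in the denominator convolution and once, reversed, in the outer
  convolution).  The unit-sum kernel normalization performed each iteration
  therefore changes nothing mathematically; it fixes a convenient gauge so
  that `o * K` is directly comparable to chi in the residual monitor.
* any solution is recoverable only up to a global cyclic translation and a
  point reflection — both leave chi unchanged.  All quantitative comparisons
  against ground truth in this package first register those two ambiguities
  (`metrics.registered_ncc` maximizes the normalized inner product over all
  cyclic shifts and both parities).

### Stopping

The solvers run fixed schedules; the energy-normalized residual is monitored
and logged at checkpoints but never used as a stopping rule.  The reference
schedule for the two-view synthetic study is 50/50 inner iterations and 2000
outer cycles (1e5 iterations per unknown).

## Boundary model

All primitives and solvers default to **circular (cyclic) transforms** at the
raster's own size, i.e. plain multiplication in the Fourier domain.  This is
the only boundary model in which the identities the algorithms rest on —
flux conservation, translation invariance of the autocorrelation, and
`chi = (o ⋆ o) * H` at fixed raster size — hold exactly.  The phantoms keep
their content away from the border, so wrap-around is immaterial for the
bundled studies.  A zero-padded linear mode (`mode="pad"`, padding to
`>= 2N-1` per axis and cropping back around the center) is available on every
operation for data that touch the raster border; the two modes agree in the
raster interior for compact content.

The zero-shift/origin convention is the center pixel, index `n // 2` per
axis.  The correlation sign convention is
`(f ⋆ g)(x) = sum_y f(y) g(y + x)`, making
`correlate(f, g) == convolve(reverse(f), g)`.

Inside the iteration drivers the arrays are cyclically shifted so the origin
sits at index 0 (all centering phase factors vanish), giving four real FFTs
per iteration; results are shifted back on exit.  Denominators are floored
at `1e-12 x max(denominator)`.  A 191x191 AU iteration costs ~4 ms on one
CPU core.

## Synthetic data generator

The generator emulates one tomographic section of a two-view light-sheet
acquisition:

* **Object** — a random arrangement of vessel-like structures on a 191x191
  raster (odd extents, so the PSF rotation axis is the central pixel):
  seeded random-walk centerlines with bounded curvature, stamped with discs
  of width 2–5 px and lightly smoothed.  Vessels are confined by a 24 px
  interior margin, keeping the raster corners signal-free for background
  estimation.  The peak is normalized to 2^16.  The generator is a
  deterministic function of its seed; the published study's exact random
  instance is not available, so agreement with its printed metrics can only
  be statistical, never bitwise.
* **PSF** — an anisotropic Gaussian with sigma = 2.7 px along the
  detection/scan axis and 1 px laterally, rotated analytically about the
  central pixel to the view angle (0 and 90 degrees by default).
* **Measurement** — the object convolved with the rotated PSF, rescaled to a
  2^16 ceiling, plus additive per-pixel Poisson noise with mean and variance
  lambda = 2^8 (the noise is a background term, not signal-dependent shot
  noise).
* **Dark frame** — a pure Poisson(lambda) raster, the no-illumination
  measurement used by the preprocessing chain.

What the generator does *not* emulate: light-sheet stripe artifacts,
absorption/scattering gradients across views, depth-dependent (anisoplanatic)
PSFs, and sub-pixel view misregistration.  Passing tests on these phantoms
demonstrate the algorithmic properties (alignment-free fusion, blind PSF
recovery, resolution gain) — not robustness to those experimental effects.

## Preprocessing chain

For each view: dark-frame subtraction clamped at zero; lossless coarse
rotation by multiples of 90 degrees; then two fusion products are formed —
the averaged absolute autocorrelation chi (no alignment), and the image-space
initial guess, built by registering every view to the reference at the
integer-pixel cross-correlation peak, compensating the shift (cyclically by
default; an edge-zeroing crop mode exists for truncated objects) and
averaging.  Exact zeros in the initial guess are replaced by 1/100 of the
image mean — zeros are fixed points of multiplicative updates and would
otherwise never move.

The dark-frame subtraction is applied to the synthetic study too: the
additive Poisson background (mean 2^8 = 256 counts) would otherwise dominate
the background region of every view and cap the measurement SNR at
20·log10(2^16/2^8) = 48.2 dB by construction.  Subtracting a simulated dark
frame (clamped difference of two Poisson fields) leaves a residual background
of ~9 counts, i.e. a measurement SNR of ~77 dB, and is exactly the
preprocessing a real acquisition undergoes.

## Metrics

* **MSE** — both the re-blurred reconstruction `o_rec * h` and the
  measurement are divided by their L2 norm; the metric is the per-pixel
  *mean* of the squared difference (`reduction="sum"` gives the plain
  squared L2 distance instead).  Scale-free by construction.
* **SNR** — `20 log10(peak / mean background)` in dB, with the background
  taken from the signal-free corner patches of the phantom rasters (any
  boolean mask can be supplied).
* **PSF characterization** — per-axis 1D Gaussian fits (amplitude, center,
  sigma, offset) through the blob maximum, by nonlinear least squares.
* **Cross orientation** — the arm orientation of a cross-shaped kernel is
  measured with a four-fold angular moment,
  `angle(sum I r^2 exp(4 i phi)) / 4`: the ordinary second-moment tensor of
  a symmetric cross is isotropic and carries no orientation, so principal
  axes cannot be used for this purpose.

## Study conditions and desk-scale schedules

The bundled studies use the conditions stated above (191x191 phantom,
sigma = (2.7, 1) px at 0/90 degrees, lambda = 2^8, object guess = aligned
fused average, PSF guess = isotropic sigma = 4 px Gaussian or a seeded
strictly-positive uniform field).  Iteration counts are scaled to the
package's own defaults for routine runs:

* test suite: 50/50 inner, 200 outer cycles (~1.5 min; the recovered PSF
  cross is already well formed — its arm orientation is within a few degrees
  and its registered NCC against the true cross exceeds 0.95);
* acceptance script: 50/50 inner, 600 outer cycles plus 1e4 RL iterations
  (~5 min);
* the full reference schedule (2000 cycles) runs in ~15 min on one core and
  changes the reported metrics only marginally (the chi-domain residual is
  already below 1e-5 at 200 cycles).

## Known limitations

* The RL comparison arm plateaus at an energy-normalized MSE floor set by
  the measurement noise (~5e-11 as a per-pixel mean under the default noise
  level); iterating past ~5e3 iterations does not reduce it.  The blind
  arm's floor is higher still, because chi (averaged per-view
  autocorrelations) and the fused image-space measurement carry different
  noise realizations.
* A spatially uniform (flat) object guess is a degenerate fixed point of the
  AU update (the effective kernel becomes constant); use a structured guess
  such as the fused measurement.
* Exact zeros in the PSF guess never grow support (multiplicative updates);
  wide Gaussian guesses whose far tails underflow to zero are fine because
  the affected pixels are far outside any plausible kernel support.
* Uniform-PSF (isoplanatic) blurring and purely rigid inter-view shifts are
  assumed throughout; rotations are only handled in multiples of 90 degrees
  (lossless axis permutations).
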