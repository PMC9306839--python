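"""Reconstruction quality metrics and Gaussian PSF characterization.

Two scalar metrics quantify the solvers' behaviour:

* the energy-normalized mean squared error between a re-blurred
  reconstruction and the measurement, ``MSE = sum((a/||a|| - b/||b||)**2)``
  (dimensionless; invariant to rescaling of either image);
* the image signal-to-noise ratio ``SNR = 20 log10(s_max / eps_bg)`` in dB,
  where ``s_max`` is the peak intensity and ``eps_bg`` the mean over a
  sample-free background region.

Also provided: per-axis 1D Gaussian fits to characterize a measured PSF
(bead image), a registered normalized cross-correlation that first resolves
the translation/reflection ambiguity inherent to autocorrelation inversion,
and a four-fold angular moment that measures the arm orientation of
cross-shaped multiview PSFs (whose ordinary second-moment tensor is
isotropic and carries no orientation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .corr import correlate, reverse

__all__ = [
    "QualityReport",
    "GaussianFit",
    "normalized_mse",
    "mse",
    "snr",
    "corner_background_mask",
    "fit_gaussian_psf",
    "registered_ncc",
    "cross_orientation",
    "angle_difference_mod90",
]


@dataclass(frozen=True)
class QualityReport:
    """MSE and SNR of a reconstruction at a given iteration."""

    mse: float
    snr_db: float
    iteration: int = 0


@dataclass(frozen=True)
class GaussianFit:
    """Per-axis 1D Gaussian fit of a single blob: center, std, amplitude, offset."""

    center: tuple[float, ...]
    sigma: tuple[float, ...]
    amplitude: float
    offset: float


def normalized_mse(a: np.ndarray, b: np.ndarray, reduction: str = "mean") -> float:
    """Squared difference of the energy-normalized rasters.

    Both inputs are divided by their L2 norm first, so the result is
    invariant to positive rescaling of either argument.  With
    ``reduction="mean"`` (default) the per-pixel mean of the squared
    difference is returned — the *mean* squared error; ``"sum"`` returns the
    plain squared L2 distance (2.0 for orthogonal unit vectors).
    """
    na = np.linalg.norm(a.ravel())
    nb = np.linalg.norm(b.ravel())
    if na == 0 or nb == 0:
        raise ValueError("cannot energy-normalize a zero-energy raster")
    d = a / na - b / nb
    total = float(np.sum(d * d))
    if reduction == "sum":
        return total
    if reduction == "mean":
        return total / d.size
    raise ValueError("reduction must be 'mean' or 'sum'")


def mse(
    o_rec: np.ndarray,
    h: np.ndarray,
    s_mu: np.ndarray,
    mode: str = "circular",
    reduction: str = "mean",
) -> float:
    """Energy-normalized MSE between the re-blurred reconstruction
    ``o_rec * h`` and the measurement ``s_mu``."""
    from .corr import convolve

    return normalized_mse(convolve(o_rec, h, mode=mode), s_mu, reduction=reduction)


def snr(image: np.ndarray, background: np.ndarray) -> float:
    """``20 log10(peak / mean background)`` in dB.

    ``background`` is a boolean mask selecting a region where the sample is
    absent; its mean estimates the background noise level.
    """
    if background.dtype != bool:
        raise ValueError("background must be a boolean mask")
    if background.shape != image.shape:
        raise ValueError("background mask shape must match the image")
    if not background.any():
        raise ValueError("background region is empty")
    eps = float(image[background].mean())
    if eps <= 0:
        raise ValueError("background mean must be positive for the SNR")
    return float(20.0 * np.log10(image.max() / eps))


def corner_background_mask(shape: tuple[int, ...], size: int = 20) -> np.ndarray:
    """Mask selecting a ``size``-pixel square patch in every corner.

    The vessel phantoms keep a signal-free margin at the raster border by
    construction, so the corner patches sample pure background.
    """
    mask = np.zeros(shape, dtype=bool)
    for idx in np.ndindex(*(2,) * len(shape)):
        sl = tuple(slice(0, size) if i == 0 else slice(n - size, n) for i, n in zip(idx, shape))
        mask[sl] = True
    return mask


def _gauss1d(x, amp, center, sigma, offset):
    return amp * np.exp(-0.5 * ((x - center) / sigma) ** 2) + offset


def fit_gaussian_psf(bead_image: np.ndarray) -> GaussianFit:
    """Characterize a single bead/PSF blob by per-axis 1D Gaussian fits.

    A 1D profile is extracted through the intensity maximum along each axis
    and fit with ``amp * exp(-(x-c)^2 / 2 sigma^2) + offset`` by nonlinear
    least squares.  Returns per-axis centers and sigmas; amplitude and
    offset are averaged over axes.
    """
    img = np.asarray(bead_image, dtype=float)
    if img.max() <= img.min():
        raise ValueError("flat image: no blob to fit")
    peak = np.unravel_index(np.argmax(img), img.shape)
    centers, sigmas, amps, offs = [], [], [], []
    for ax in range(img.ndim):
        idx = list(peak)
        idx[ax] = slice(None)
        profile = img[tuple(idx)]
        x = np.arange(profile.size, dtype=float)
        offset0 = float(profile.min())
        amp0 = float(profile.max() - offset0)
        w = np.clip(profile - offset0, 0, None)
        sigma0 = float(np.sqrt(np.sum(w * (x - peak[ax]) ** 2) / w.sum())) or 1.0
        try:
            popt, _ = curve_fit(
                _gauss1d,
                x,
                profile,
                p0=(amp0, float(peak[ax]), sigma0, offset0),
                maxfev=10000,
            )
        except RuntimeError as exc:
            resid = profile - _gauss1d(x, amp0, peak[ax], sigma0, offset0)
            raise RuntimeError(
                f"Gaussian fit failed along axis {ax}: {exc}; "
                f"initial-guess residual RMS {np.sqrt(np.mean(resid ** 2)):.3g}"
            ) from exc
        amp, center, sigma, offset = popt
        if sigma <= 0:
            sigma = abs(sigma)
        centers.append(float(center))
        sigmas.append(float(sigma))
        amps.append(float(amp))
        offs.append(float(offset))
    return GaussianFit(tuple(centers), tuple(sigmas), float(np.mean(amps)), float(np.mean(offs)))


def registered_ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation after registering the trivial ambiguities.

    Autocorrelation inversion recovers images only up to cyclic translation
    and point reflection.  This returns the maximum of
    ``sum(a · shift(b')) / (||a|| ||b||)`` over all cyclic shifts and over
    ``b' in {b, reverse(b)}`` — 1.0 means a perfect match up to those
    transformations (for nonnegative images).
    """
    na = np.linalg.norm(a.ravel())
    nb = np.linalg.norm(b.ravel())
    if na == 0 or nb == 0:
        raise ValueError("cannot normalize a zero-energy raster")
    best = -np.inf
    for cand in (b, reverse(b)):
        xc = correlate(a, cand, mode="circular")
        best = max(best, float(xc.max()))
    return best / (na * nb)


def cross_orientation(psf: np.ndarray) -> float:
    """Arm orientation (degrees, in [-45, 45)) of a cross-shaped kernel.

    The second-moment tensor of a symmetric cross (two orthogonal elongated
    lobes of equal weight) is isotropic, so principal axes carry no
    information.  The four-fold angular moment
    ``S = sum I(r, phi) r^2 exp(4 i phi)`` does: its phase/4 gives the common
    orientation of the orthogonal arm pair (0 for arms along the image axes,
    45 for a diagonal cross).  Coordinates are taken about the intensity
    centroid.
    """
    img = np.asarray(psf, dtype=float)
    total = img.sum()
    if total <= 0:
        raise ValueError("kernel must have positive total intensity")
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in img.shape], indexing="ij")
    centroid = [float((g * img).sum() / total) for g in grids]
    dz = grids[0] - centroid[0]
    dx = grids[1] - centroid[1]
    r2 = dz**2 + dx**2
    phi = np.arctan2(dx, dz)
    S = np.sum(img * r2 * np.exp(4j * phi))
    return float(np.rad2deg(np.angle(S)) / 4.0)


def angle_difference_mod90(a_deg: float, b_deg: float) -> float:
    """Smallest difference between two orientations defined modulo 90 degrees."""
    d = abs(a_deg - b_deg) % 90.0
    return min(d, 90.0 - d)
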