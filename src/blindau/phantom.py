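"""Synthetic vessel phantoms, parametric PSFs, and simulated measurements.

This module emulates a tomographic section of a light-sheet acquisition: a 2D
object made of vessel-like curvilinear structures is blurred by an anisotropic
Gaussian point spread function elongated along the detection/scan axis,
normalized to a 16-bit ceiling, and corrupted by additive Poisson noise.  One
such measurement is produced per view angle; orthogonal views differ only by
the rotation of the PSF.

Defaults follow the simulation conditions of the study this package
reproduces: 191 x 191 px rasters (odd, so the PSF rotates about the central
pixel), PSF standard deviations (sigma_axial, sigma_lateral) = (2.7, 1) px,
view angles 0 and 90 degrees, intensity ceiling 2**16 and Poisson noise with
mean and variance lambda = 2**8.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .corr import convolve

__all__ = [
    "PsfModel",
    "PhantomSpec",
    "rasterize_psf",
    "make_vessel_phantom",
    "two_wall_phantom",
    "simulate_view",
    "simulate_dark",
]

DEFAULT_SHAPE = (191, 191)
DEFAULT_INTENSITY_MAX = 2.0**16
DEFAULT_NOISE_MEAN = 2.0**8


@dataclass(frozen=True)
class PsfModel:
    """Anisotropic Gaussian PSF: std per axis plus an in-plane rotation.

    ``sigma_axial`` is the std along the detection/scan axis (image rows at
    ``theta=0``), ``sigma_lateral`` along the orthogonal axis.  ``theta`` is
    the view angle in degrees; the rotation is applied analytically about the
    central pixel, so odd extents are required.
    """

    sigma_axial: float = 2.7
    sigma_lateral: float = 1.0
    theta: float = 0.0
    shape: tuple[int, int] = DEFAULT_SHAPE

    def __post_init__(self) -> None:
        if self.sigma_axial <= 0 or self.sigma_lateral <= 0:
            raise ValueError("PSF standard deviations must be positive")
        if any(n % 2 == 0 for n in self.shape):
            raise ValueError(
                "PSF raster extents must be odd so the Gaussian is symmetric "
                "about the central pixel"
            )


def rasterize_psf(model: PsfModel) -> np.ndarray:
    """Sample the rotated anisotropic Gaussian on the raster; unit sum.

    The Gaussian is evaluated analytically on coordinates rotated by
    ``theta`` about the central pixel — no interpolation, so ``theta=90`` on a
    square raster is exactly the transpose of ``theta=0``.
    """
    nz, nx = model.shape
    z = np.arange(nz) - nz // 2
    x = np.arange(nx) - nx // 2
    zz, xx = np.meshgrid(z, x, indexing="ij")
    t = np.deg2rad(model.theta)
    # coordinates in the PSF's own frame (axial, lateral)
    za = np.cos(t) * zz + np.sin(t) * xx
    xl = -np.sin(t) * zz + np.cos(t) * xx
    g = np.exp(-0.5 * (za / model.sigma_axial) ** 2 - 0.5 * (xl / model.sigma_lateral) ** 2)
    return g / g.sum()


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the random vessel phantom and its simulated measurement."""

    shape: tuple[int, int] = DEFAULT_SHAPE
    structure_count: int = 8
    vessel_width_range: tuple[float, float] = (2.0, 5.0)
    intensity_max: float = DEFAULT_INTENSITY_MAX
    noise_mean: float = DEFAULT_NOISE_MEAN
    angles: tuple[float, ...] = (0.0, 90.0)
    margin: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intensity_max <= 0:
            raise ValueError("intensity_max must be positive")
        if self.noise_mean < 0:
            raise ValueError("noise_mean must be nonnegative")
        if any(n % 2 == 0 for n in self.shape):
            raise ValueError("phantom extents must be odd")


def make_vessel_phantom(spec: PhantomSpec) -> np.ndarray:
    """Random arrangement of smooth vessel-like tubes, peak-normalized.

    Centerlines are seeded random walks with bounded curvature, confined to
    the raster interior by a ``margin`` (keeping the corners signal-free for
    background/noise estimation).  Each centerline is stamped with a disc of
    its vessel half-width and the result lightly Gaussian-smoothed, giving
    tubular structures with soft edges.  Deterministic function of
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    canvas = np.zeros(spec.shape, dtype=float)
    if spec.structure_count == 0:
        warnings.warn("structure_count is 0: returning an all-zero phantom")
        return canvas

    nz, nx = spec.shape
    lo = spec.margin
    hi_z, hi_x = nz - 1 - spec.margin, nx - 1 - spec.margin
    yy, xx = np.mgrid[0:nz, 0:nx]

    for _ in range(spec.structure_count):
        width = rng.uniform(*spec.vessel_width_range)
        radius = width / 2.0
        pos = np.array([rng.uniform(lo, hi_z), rng.uniform(lo, hi_x)])
        heading = rng.uniform(0, 2 * np.pi)
        n_steps = rng.integers(60, 160)
        step = 1.0
        pts = []
        for _ in range(n_steps):
            heading += rng.normal(0.0, 0.12)  # bounded curvature
            pos = pos + step * np.array([np.sin(heading), np.cos(heading)])
            # reflect off the interior margin so corners stay empty
            for ax, (a, b) in enumerate(((lo, hi_z), (lo, hi_x))):
                if pos[ax] < a:
                    pos[ax] = 2 * a - pos[ax]
                    heading = -heading if ax == 0 else np.pi - heading
                elif pos[ax] > b:
                    pos[ax] = 2 * b - pos[ax]
                    heading = -heading if ax == 0 else np.pi - heading
            pts.append(pos.copy())
        pts = np.array(pts)
        # stamp a disc of the vessel radius at every centerline sample
        tube = np.zeros(spec.shape, dtype=bool)
        for pz, px in pts:
            mask = (yy - pz) ** 2 + (xx - px) ** 2 <= radius**2
            tube |= mask
        canvas += tube.astype(float) * rng.uniform(0.55, 1.0)

    canvas = ndimage.gaussian_filter(canvas, sigma=0.8)
    peak = canvas.max()
    if peak > 0:
        canvas *= spec.intensity_max / peak
    return canvas


def two_wall_phantom(
    shape: tuple[int, int] = DEFAULT_SHAPE,
    separation: float = 7.0,
    width: float = 2.0,
    length: int = 60,
    orientation_deg: float = 0.0,
    intensity_max: float = DEFAULT_INTENSITY_MAX,
) -> np.ndarray:
    """Synthetic resolution target: two parallel vessel walls.

    Two straight tubes of the given ``width`` run parallel at the stated
    center-to-center ``separation`` (px, measured along the common normal),
    centered on the raster and rotated by ``orientation_deg`` (0 = vertical
    walls separated horizontally; 45 = diagonal walls, blurred equally by
    the two orthogonal light-sheet PSFs).  Blurred by an elongated PSF the
    pair merges into a single hump; a successful deconvolution must recover
    the two maxima.
    """
    nz, nx = shape
    canvas = np.zeros(shape, dtype=float)
    yy, xx = np.mgrid[0:nz, 0:nx]
    cz, cx = nz // 2, nx // 2
    t = np.deg2rad(orientation_deg)
    # unit vectors along the walls and along their common normal
    along = (np.cos(t) * (yy - cz) + np.sin(t) * (xx - cx))
    across = (-np.sin(t) * (yy - cz) + np.cos(t) * (xx - cx))
    half = separation / 2.0
    for off in (-half, half):
        band = (np.abs(across - off) <= width / 2.0) & (np.abs(along) <= length / 2.0)
        canvas[band] = 1.0
    canvas = ndimage.gaussian_filter(canvas, sigma=0.6)
    canvas *= intensity_max / canvas.max()
    return canvas


def simulate_view(
    obj: np.ndarray,
    psf: PsfModel,
    noise_mean: float = DEFAULT_NOISE_MEAN,
    seed: int = 0,
    intensity_max: float = DEFAULT_INTENSITY_MAX,
    mode: str = "circular",
) -> np.ndarray:
    """One simulated measurement: ``f = o * h_theta + eps``.

    The object is convolved with the rasterized PSF, rescaled so its maximum
    equals ``intensity_max``, and additive Poisson noise with mean and
    variance ``noise_mean`` is drawn per pixel.  Values stay floating point.
    """
    if noise_mean < 0:
        raise ValueError("noise_mean must be nonnegative")
    h = rasterize_psf(psf)
    if obj.shape != h.shape:
        raise ValueError(f"object shape {obj.shape} != PSF raster shape {h.shape}")
    blurred = convolve(obj, h, mode=mode)
    np.maximum(blurred, 0.0, out=blurred)  # round-off guard
    peak = blurred.max()
    if peak > 0:
        blurred *= intensity_max / peak
    if noise_mean > 0:
        rng = np.random.default_rng(seed)
        blurred = blurred + rng.poisson(noise_mean, size=blurred.shape)
    return blurred


def simulate_dark(
    shape: tuple[int, int],
    noise_mean: float = DEFAULT_NOISE_MEAN,
    seed: int = 0,
) -> np.ndarray:
    """A no-illumination (dark) measurement: pure Poisson noise of the camera.

    Used as the synthetic analog of the dark stack acquired for background
    subtraction in the preprocessing chain.
    """
    rng = np.random.default_rng(seed)
    return rng.poisson(noise_mean, size=shape).astype(float)
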