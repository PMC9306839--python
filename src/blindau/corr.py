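"""Fourier-domain convolution and correlation primitives.

All rasters are plain ``numpy`` arrays of nonnegative intensities.  Every
operation here shares one spatial convention: the zero-shift / kernel-origin
pixel is the *center* pixel of the raster, index ``n // 2`` along each axis.
With this convention a unit impulse placed at the center is the identity
element of :func:`convolve`, and autocorrelations come out point-symmetric
about the center pixel.

Two boundary models are available:

``mode="circular"`` (default)
    Plain cyclic transforms on the raster as given — convolution and
    correlation are multiplications in the Fourier domain at the raster's own
    size.  All algebraic identities (flux, shift invariance,
    ``chi = (o ⋆ o) * H``) hold exactly in this mode, which is why the
    iterative solvers use it.

``mode="pad"``
    Linear (aperiodic) convolution/correlation computed on a zero-padded grid
    of at least ``2n - 1`` samples per axis, cropped back to the input extent
    around the center.  Use this when wrap-around from objects touching the
    raster border would be harmful.

The correlation sign convention is ``(f ⋆ g)(x) = sum_y f(y) g(y + x)``, so
that ``correlate(f, g) == convolve(reverse(f), g)``.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sp_fft

__all__ = [
    "center_index",
    "convolve",
    "correlate",
    "autocorrelate",
    "reverse",
]

_MODES = ("circular", "pad")


def center_index(shape: tuple[int, ...]) -> tuple[int, ...]:
    """Index of the zero-shift (center) pixel: ``n // 2`` per axis."""
    return tuple(n // 2 for n in shape)


def _check_pair(f: np.ndarray, g: np.ndarray) -> None:
    if f.shape != g.shape:
        raise ValueError(f"shape mismatch: {f.shape} vs {g.shape}")
    if f.size == 0:
        raise ValueError("empty raster")


def _check_mode(mode: str) -> None:
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")


def reverse(f: np.ndarray) -> np.ndarray:
    """Point reflection of ``f`` through the center pixel.

    Maps index ``x`` to ``(2c - x) mod n`` with ``c = n // 2``, so the center
    pixel is a fixed point and ``reverse(reverse(f)) == f``.
    """
    out = np.flip(f)
    # flip gives f[n-1-x]; for even axes the center n//2 sits one pixel off
    for ax, n in enumerate(f.shape):
        c = n // 2
        shift = 2 * c + 1 - n  # 0 for odd extents, 1 for even
        if shift:
            out = np.roll(out, shift, axis=ax)
    return out


def _pad_slices(shape: tuple[int, ...], kind: str) -> tuple[slice, ...]:
    # crop window of the full linear result, centered per our convention
    out = []
    for n in shape:
        c = n // 2
        start = c if kind == "conv" else (n - 1 - c)
        out.append(slice(start, start + n))
    return tuple(out)


def convolve(f: np.ndarray, g: np.ndarray, mode: str = "circular") -> np.ndarray:
    """Convolution ``(f * g)(x) = sum_y f(y) g(x - y)`` with centered origin.

    A unit impulse at the center pixel is the identity.  In circular mode
    ``sum(f * g) == sum(f) * sum(g)`` exactly (up to round-off).
    """
    _check_pair(f, g)
    _check_mode(mode)
    if mode == "pad":
        full = _linear_fft_op(f, g, conjugate_first=False)
        return full[_pad_slices(f.shape, "conv")]
    F = sp_fft.rfftn(f)
    G = sp_fft.rfftn(g)
    out = sp_fft.irfftn(F * G, s=f.shape)
    return np.roll(out, [-c for c in center_index(f.shape)], axis=range(f.ndim))


def correlate(f: np.ndarray, g: np.ndarray, mode: str = "circular") -> np.ndarray:
    """Cross-correlation ``(f ⋆ g)(x) = sum_y f(y) g(y + x)``.

    Zero shift is mapped to the center pixel, so
    ``correlate(f, f)[center] == sum(f**2)``.
    """
    _check_pair(f, g)
    _check_mode(mode)
    if mode == "pad":
        full = _linear_fft_op(f, g, conjugate_first=True)
        return full[_pad_slices(f.shape, "corr")]
    F = sp_fft.rfftn(f)
    G = sp_fft.rfftn(g)
    out = sp_fft.irfftn(np.conj(F) * G, s=f.shape)
    return np.roll(out, center_index(f.shape), axis=range(f.ndim))


def _linear_fft_op(f: np.ndarray, g: np.ndarray, conjugate_first: bool) -> np.ndarray:
    """Full linear convolution (or correlation) of equal-shape rasters via FFT."""
    full_shape = tuple(2 * n - 1 for n in f.shape)
    fast = [sp_fft.next_fast_len(n) for n in full_shape]
    G = sp_fft.rfftn(g, s=fast)
    if conjugate_first:
        # corr_full[k] = sum_y f(y) g(y + k - (n-1)); realized as conv with flip
        spec = sp_fft.rfftn(np.flip(f), s=fast) * G
    else:
        spec = sp_fft.rfftn(f, s=fast) * G
    out = sp_fft.irfftn(spec, s=fast)
    return out[tuple(slice(0, n) for n in full_shape)]


def autocorrelate(f: np.ndarray, mode: str = "circular") -> np.ndarray:
    """Autocorrelation ``f ⋆ f`` with zero shift at the center pixel.

    The result is point-symmetric about the center and attains its global
    maximum there.  In circular mode it is invariant under any cyclic
    translation of ``f`` and under point reflection of ``f``.
    """
    if f.size == 0:
        raise ValueError("empty raster")
    return correlate(f, f, mode=mode)
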