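"""Multiview preprocessing: background subtraction, rotation, alignment,
fusion, and the averaged-autocorrelation fusion target.

A multiview acquisition is a set of rasters of one object taken at different
angles.  Image-space fusion (used for the initial object guess) requires
rigid alignment; the averaged autocorrelation used by the autocorrelation
solvers does not — translations drop out of autocorrelations, which is the
point of working in shift space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corr import autocorrelate, center_index, correlate

__all__ = [
    "ViewSet",
    "subtract_background",
    "coarse_rotate",
    "register_translation",
    "apply_shift",
    "align_views",
    "fuse_aligned",
    "average_autocorrelation",
    "floor_zeros",
]


@dataclass
class ViewSet:
    """A list of same-shape views with their acquisition angles."""

    views: list[np.ndarray]
    angles: list[float] = field(default_factory=list)
    reference_index: int = 0

    def __post_init__(self) -> None:
        if len(self.views) < 1:
            raise ValueError("a ViewSet needs at least one view")
        shape = self.views[0].shape
        if any(v.shape != shape for v in self.views):
            raise ValueError("all views must share one shape")
        if not self.angles:
            self.angles = [0.0] * len(self.views)

    def __len__(self) -> int:
        return len(self.views)


def subtract_background(view: np.ndarray, dark: np.ndarray) -> np.ndarray:
    """Subtract a dark (no-illumination) raster, clamping at zero."""
    if view.shape != dark.shape:
        raise ValueError(f"shape mismatch: {view.shape} vs {dark.shape}")
    return np.clip(view - dark, 0.0, None)


def coarse_rotate(view: np.ndarray, quarter_turns: int) -> np.ndarray:
    """Lossless rotation by multiples of 90 degrees (no interpolation).

    Rotates in the last two axes, so 3D stacks rotate slice-wise about the
    stack axis.  Four quarter turns are the identity.
    """
    return np.rot90(view, k=int(quarter_turns) % 4, axes=(-2, -1))


def register_translation(reference: np.ndarray, moving: np.ndarray) -> tuple[int, ...]:
    """Integer shift at the cross-correlation peak.

    Returns ``delta`` such that ``moving ≈ roll(reference, delta)``; applying
    the opposite shift to ``moving`` (see :func:`apply_shift`) maximizes its
    overlap with ``reference``.  Shift components are reported in
    ``[-n/2, n/2)`` per axis.
    """
    if reference.shape != moving.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {moving.shape}")
    if not np.any(reference) or not np.any(moving):
        raise ValueError("cannot register an all-zero raster (undefined peak)")
    xc = correlate(reference, moving)
    peak = np.unravel_index(np.argmax(xc), xc.shape)
    center = center_index(xc.shape)
    return tuple(int(p - c) for p, c in zip(peak, center))


def apply_shift(view: np.ndarray, shift: tuple[int, ...], crop: bool = False) -> np.ndarray:
    """Compensate a registered shift: cyclically roll ``view`` by ``-shift``.

    With ``crop=True`` the pixels wrapped around the border are zeroed
    instead of reentering on the opposite side (useful for truncated
    objects).
    """
    compensated = np.roll(view, [-s for s in shift], axis=range(view.ndim))
    if crop:
        compensated = compensated.copy()
        for ax, s in enumerate(shift):
            if s > 0:
                idx = [slice(None)] * view.ndim
                idx[ax] = slice(view.shape[ax] - s, None)
                compensated[tuple(idx)] = 0.0
            elif s < 0:
                idx = [slice(None)] * view.ndim
                idx[ax] = slice(0, -s)
                compensated[tuple(idx)] = 0.0
    return compensated


def align_views(views: ViewSet, crop: bool = False) -> ViewSet:
    """Register every view against the reference and compensate its shift."""
    ref = views.views[views.reference_index]
    aligned = []
    for i, v in enumerate(views.views):
        if i == views.reference_index:
            aligned.append(v.copy())
            continue
        shift = register_translation(ref, v)
        aligned.append(apply_shift(v, shift, crop=crop))
    return ViewSet(aligned, list(views.angles), views.reference_index)


def fuse_aligned(views: ViewSet) -> np.ndarray:
    """Pixel-wise mean of the (already aligned) views."""
    return np.mean(views.views, axis=0)


def average_autocorrelation(views: ViewSet, mode: str = "circular") -> np.ndarray:
    """The fusion target chi: mean over views of |autocorrelation|.

    No alignment is performed — autocorrelation is invariant to (cyclic)
    translation, so misregistered views contribute identically.  The absolute
    value guards against tiny negative round-off before averaging, keeping
    chi a valid nonnegative correlation field.
    """
    acc = None
    for v in views.views:
        a = np.abs(autocorrelate(v, mode=mode))
        acc = a if acc is None else acc + a
    return acc / len(views)


def floor_zeros(image: np.ndarray) -> np.ndarray:
    """Replace exact zeros by 1/100 of the image mean.

    Multiplicative updates leave zero pixels at zero forever; a small
    positive floor lets the solvers move them.  Rejects all-zero images
    (the floor would be undefined).
    """
    if not np.any(image > 0):
        raise ValueError("floor_zeros requires at least one positive pixel")
    floor = image.mean() / 100.0
    out = image.astype(float, copy=True)
    out[out == 0] = floor
    return out
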