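"""Iterative solvers: Richardson–Lucy deconvolution, Anchor-Update
autocorrelation inversion, and the alternating blind scheme (Blind-AU).

All three are multiplicative fixed-point schemes.  Richardson–Lucy inverts an
image-space blur ``f = o * h``:

    o_{t+1} = o_t · [ (f / (o_t * h)) * h~ ]

where ``h~`` is the kernel with reversed coordinates.  The Anchor-Update (AU)
scheme inverts a *blurred autocorrelation* ``chi = (o ⋆ o) * H`` (with
``H = h ⋆ h``) by the same structure, but with an effective kernel that is
continuously rebuilt from the current iterate, ``K_t = o_t ⋆ H``:

    o_{t+1} = o_t · [ (chi / (o_t * K_t)) * K~_t ]

Blind-AU alternates two AU blocks on the single measured quantity chi: a
block updating the object with the PSF (hence ``H``) frozen, then a block
updating the PSF with the object (hence ``O = o ⋆ o``) frozen.  Neither the
object nor the PSF need be known in advance.

Properties shared by all updates: nonnegativity of the iterates is preserved
(every factor is nonnegative), and total flux locks onto the value implied by
the data after the first iteration (``sum(f)`` for RL, ``sum(chi)`` for AU)
and is conserved thereafter under cyclic boundaries.  Because the update is
invariant to rescaling of the kernel, kernels are normalized to unit sum
purely for numerical hygiene and interpretability of the residual trace.

Solutions of the autocorrelation problem are intrinsically ambiguous up to
cyclic translation and point reflection; compare reconstructions to ground
truth only after registering those (see :func:`blindau.metrics.registered_ncc`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft

from .corr import autocorrelate, convolve, correlate, reverse
from .metrics import normalized_mse

__all__ = [
    "BlindSchedule",
    "ReconstructionState",
    "rl_step",
    "rl_deconvolve",
    "au_kernel",
    "au_step",
    "au_deconvolve",
    "blind_au",
]

#: relative floor applied to denominators of the multiplicative updates
EPS_REL = 1e-12


@dataclass(frozen=True)
class BlindSchedule:
    """Iteration schedule of the alternating blind scheme.

    ``object_inner_iters`` (t) and ``psf_inner_iters`` (t') are the AU
    iterations spent per block; ``outer_cycles`` (k) is the number of
    object/PSF alternations.  The reference schedule of the synthetic study
    is 50/50 inner steps and 2000 cycles — 1e5 iterations per unknown.
    """

    object_inner_iters: int = 50
    psf_inner_iters: int = 50
    outer_cycles: int = 2000
    checkpoint_every: int = 10

    def __post_init__(self) -> None:
        for name in ("object_inner_iters", "psf_inner_iters", "outer_cycles", "checkpoint_every"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def total_iterations(self) -> int:
        return (self.object_inner_iters + self.psf_inner_iters) * self.outer_cycles


@dataclass
class ReconstructionState:
    """Result of a Blind-AU run: final estimates plus checkpoint history."""

    object_estimate: np.ndarray
    psf_estimate: np.ndarray
    chi: np.ndarray
    cycle_index: int
    history: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# single-step operations (centered convention, built on the corr primitives)
# ---------------------------------------------------------------------------

def _floored(denom: np.ndarray) -> np.ndarray:
    eps = EPS_REL * float(denom.max())
    if eps <= 0:
        raise ValueError("update denominator is identically zero")
    return np.maximum(denom, eps)


def rl_step(o_t: np.ndarray, f_mu: np.ndarray, h: np.ndarray, mode: str = "circular") -> np.ndarray:
    """One Richardson–Lucy update ``o · [(f / (o * h)) * h~]``."""
    denom = _floored(convolve(o_t, h, mode=mode))
    ratio = f_mu / denom
    update = convolve(ratio, reverse(h), mode=mode)
    return o_t * np.maximum(update, 0.0)


def au_kernel(current: np.ndarray, fixed_autocorr: np.ndarray, mode: str = "circular") -> np.ndarray:
    """Effective AU kernel ``K = current ⋆ fixed_autocorr``, unit sum.

    The update itself is invariant to the kernel's scale (the kernel enters
    once in the denominator and once reversed in the outer convolution), so
    the unit-sum normalization only fixes a convenient gauge.
    """
    K = correlate(current, fixed_autocorr, mode=mode)
    s = K.sum()
    if not np.isfinite(s) or s <= 0:
        raise ValueError("AU kernel has nonpositive sum; cannot normalize")
    return K / s


def au_step(o_t: np.ndarray, chi: np.ndarray, K_t: np.ndarray, mode: str = "circular") -> np.ndarray:
    """One Anchor-Update step ``o · [(chi / (o * K)) * K~]``."""
    denom = _floored(convolve(o_t, K_t, mode=mode))
    ratio = chi / denom
    update = convolve(ratio, reverse(K_t), mode=mode)
    return o_t * np.maximum(update, 0.0)


# ---------------------------------------------------------------------------
# iteration drivers
#
# In circular mode the drivers run an equivalent origin-at-zero Fourier loop
# (arrays entering the loop are ifftshift-ed, results fftshift-ed back):
# translating every raster by the same amount commutes with convolution and
# correlation, and with the origin at index 0 all centering phase factors
# vanish, leaving 4 real FFTs per iteration.
# ---------------------------------------------------------------------------

def _shift_in(a: np.ndarray) -> np.ndarray:
    return np.fft.ifftshift(a)


def _shift_out(a: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(a)


def rl_deconvolve(
    f_mu: np.ndarray,
    h: np.ndarray,
    n_iter: int,
    o0: np.ndarray | None = None,
    mode: str = "circular",
) -> tuple[np.ndarray, np.ndarray]:
    """Run ``n_iter`` RL iterations; return the estimate and the MSE trace.

    The trace holds, per iteration, the energy-normalized mean squared error
    between the current re-blurred estimate ``o_t * h`` and the measurement.
    ``o0`` defaults to the measurement itself with zeros floored.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if o0 is None:
        from .multiview import floor_zeros

        o0 = floor_zeros(f_mu)
    elif np.any(o0 < 0):
        raise ValueError("initial object guess must be nonnegative")

    if mode != "circular":
        o = o0.astype(float, copy=True)
        trace = np.empty(n_iter)
        for t in range(n_iter):
            trace[t] = normalized_mse(convolve(o, h, mode=mode), f_mu)
            o = rl_step(o, f_mu, h, mode=mode)
        return o, trace

    o = _shift_in(o0).astype(float)
    f_w = _shift_in(f_mu).astype(float)
    Fh = sp_fft.rfftn(_shift_in(h))
    trace = np.empty(n_iter)
    for t in range(n_iter):
        Fo = sp_fft.rfftn(o)
        denom = sp_fft.irfftn(Fo * Fh, s=o.shape)
        trace[t] = normalized_mse(denom, f_w)
        ratio = f_w / _floored(denom)
        update = sp_fft.irfftn(sp_fft.rfftn(ratio) * np.conj(Fh), s=o.shape)
        o *= np.maximum(update, 0.0)
    return _shift_out(o), trace


def _au_iterate(
    o_w: np.ndarray,
    chi_w: np.ndarray,
    FH: np.ndarray,
    n_iter: int,
) -> float:
    """In-place origin-at-zero AU iterations with frozen ``FH``.

    Returns the energy-normalized residual between ``o * K`` and chi at the
    last iteration (a convergence monitor that is free to compute).
    """
    residual = np.nan
    zero = (0,) * o_w.ndim
    for _ in range(n_iter):
        Fo = sp_fft.rfftn(o_w)
        Kspec = np.conj(Fo) * FH
        s = Kspec[zero].real
        if not np.isfinite(s) or s <= 0:
            raise ValueError("AU kernel has nonpositive sum; cannot normalize")
        Kspec /= s
        denom = sp_fft.irfftn(Fo * Kspec, s=o_w.shape)
        residual = normalized_mse(denom, chi_w)
        ratio = chi_w / _floored(denom)
        update = sp_fft.irfftn(sp_fft.rfftn(ratio) * np.conj(Kspec), s=o_w.shape)
        o_w *= np.maximum(update, 0.0)
    return residual


def au_deconvolve(
    chi: np.ndarray,
    psf: np.ndarray,
    o0: np.ndarray,
    n_iter: int,
    mode: str = "circular",
) -> tuple[np.ndarray, np.ndarray]:
    """Known-PSF autocorrelation inversion: recover ``o`` from chi and ``h``.

    ``H = h ⋆ h`` is frozen; each iteration rebuilds the effective kernel
    ``K_t = o_t ⋆ H`` and applies :func:`au_step`.  Returns the estimate and
    the per-iteration residual trace (energy-normalized MSE between
    ``o_t * K_t`` and chi).  The reconstruction carries the intrinsic
    translation/reflection ambiguity of autocorrelations.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if np.any(o0 < 0):
        raise ValueError("initial object guess must be nonnegative")

    if mode != "circular":
        H = autocorrelate(psf, mode=mode)
        o = o0.astype(float, copy=True)
        trace = np.empty(n_iter)
        for t in range(n_iter):
            K = au_kernel(o, H, mode=mode)
            trace[t] = normalized_mse(convolve(o, K, mode=mode), chi)
            o = au_step(o, chi, K, mode=mode)
        return o, trace

    o_w = _shift_in(o0).astype(float)
    chi_w = _shift_in(chi).astype(float)
    Fh = sp_fft.rfftn(psf)
    FH = (Fh * np.conj(Fh)).real  # spectrum of H = h ⋆ h, roll-invariant
    trace = np.empty(n_iter)
    for t in range(n_iter):
        trace[t] = _au_iterate(o_w, chi_w, FH, 1)
    return _shift_out(o_w), trace


def blind_au(
    chi: np.ndarray,
    o0: np.ndarray,
    h0: np.ndarray,
    schedule: BlindSchedule,
    mode: str = "circular",
) -> ReconstructionState:
    """Alternating blind inversion of the averaged autocorrelation chi.

    Each outer cycle runs ``t`` object iterations with the PSF frozen
    (kernel ``K = o ⋆ H``, ``H`` recomputed from the current PSF once per
    block) followed by ``t'`` PSF iterations with the object frozen (kernel
    ``K' = h ⋆ O``, ``O`` recomputed once per block).  The PSF estimate is
    renormalized to unit sum at the end of each PSF block; the object's
    scale is left to be fixed by chi.

    Both initial guesses must be strictly positive (use
    :func:`blindau.multiview.floor_zeros` on the object guess): zeros are
    fixed points of multiplicative updates.
    """
    if chi.shape != o0.shape or chi.shape != h0.shape:
        raise ValueError("chi, o0 and h0 must share one shape")
    if not np.all(o0 > 0):
        raise ValueError("o0 must be strictly positive (apply floor_zeros first)")
    if np.any(h0 < 0) or h0.sum() <= 0:
        raise ValueError("h0 must be nonnegative with positive sum")
    # exact zeros in h0 are fixed points of the multiplicative update: the PSF
    # estimate can never grow support there (harmless for guesses whose far
    # tails underflow, e.g. a wide Gaussian on a large raster)

    if mode != "circular":
        return _blind_au_generic(chi, o0, h0, schedule, mode)

    o_w = _shift_in(o0).astype(float)
    h_w = _shift_in(h0).astype(float)
    h_w /= h_w.sum()
    chi_w = _shift_in(chi).astype(float)
    history: list[dict] = []

    for k in range(1, schedule.outer_cycles + 1):
        Fh = sp_fft.rfftn(h_w)
        FH = (Fh * np.conj(Fh)).real
        res_obj = _au_iterate(o_w, chi_w, FH, schedule.object_inner_iters)

        Fo = sp_fft.rfftn(o_w)
        FO = (Fo * np.conj(Fo)).real
        res_psf = _au_iterate(h_w, chi_w, FO, schedule.psf_inner_iters)
        h_w /= h_w.sum()

        if k % schedule.checkpoint_every == 0 or k == schedule.outer_cycles:
            history.append(
                {
                    "cycle": k,
                    "residual_object": float(res_obj),
                    "residual_psf": float(res_psf),
                    "object_flux": float(o_w.sum()),
                }
            )

    return ReconstructionState(
        object_estimate=_shift_out(o_w),
        psf_estimate=_shift_out(h_w),
        chi=chi,
        cycle_index=schedule.outer_cycles,
        history=history,
    )


def _blind_au_generic(
    chi: np.ndarray,
    o0: np.ndarray,
    h0: np.ndarray,
    schedule: BlindSchedule,
    mode: str,
) -> ReconstructionState:
    """Reference (non-fast-path) Blind-AU loop built on the step operations."""
    o = o0.astype(float, copy=True)
    h = h0.astype(float) / h0.sum()
    history: list[dict] = []
    for k in range(1, schedule.outer_cycles + 1):
        H = autocorrelate(h, mode=mode)
        res_obj = np.nan
        for _ in range(schedule.object_inner_iters):
            K = au_kernel(o, H, mode=mode)
            res_obj = normalized_mse(convolve(o, K, mode=mode), chi)
            o = au_step(o, chi, K, mode=mode)
        O = autocorrelate(o, mode=mode)
        res_psf = np.nan
        for _ in range(schedule.psf_inner_iters):
            K = au_kernel(h, O, mode=mode)
            res_psf = normalized_mse(convolve(h, K, mode=mode), chi)
            h = au_step(h, chi, K, mode=mode)
        h /= h.sum()
        if k % schedule.checkpoint_every == 0 or k == schedule.outer_cycles:
            history.append(
                {
                    "cycle": k,
                    "residual_object": float(res_obj),
                    "residual_psf": float(res_psf),
                    "object_flux": float(o.sum()),
                }
            )
    return ReconstructionState(o, h, chi, schedule.outer_cycles, history)
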