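"""Solver correctness: single-step oracles, fixed points, flux, recovery."""

import numpy as np
import pytest

from blindau import (
    BlindSchedule,
    PsfModel,
    au_deconvolve,
    au_kernel,
    au_step,
    autocorrelate,
    blind_au,
    convolve,
    rasterize_psf,
    registered_ncc,
    reverse,
    rl_deconvolve,
    rl_step,
)
from conftest import conv_oracle_1d, corr_oracle_1d, reverse_oracle_1d


def rl_step_oracle_1d(o, f, h):
    """Direct-sum multiplicative RL update on a 1D raster."""
    denom = conv_oracle_1d(o, h)
    denom = np.maximum(denom, 1e-12 * denom.max())
    return o * conv_oracle_1d(f / denom, reverse_oracle_1d(h))


def au_step_oracle_1d(o, chi, K):
    denom = conv_oracle_1d(o, K)
    denom = np.maximum(denom, 1e-12 * denom.max())
    return o * conv_oracle_1d(chi / denom, reverse_oracle_1d(K))


@pytest.fixture
def problem_1d():
    rng = np.random.default_rng(3)
    o = np.zeros(8)
    o[[2, 5]] = [1.0, 0.7]
    h = np.array([0.05, 0.1, 0.2, 0.3, 0.2, 0.1, 0.05, 0.0])
    h = h / h.sum()
    f = conv_oracle_1d(o, h)
    return o, h, f, rng


class TestSingleStepOracles:
    def test_rl_step_matches_loop_oracle(self, problem_1d):
        o, h, f, rng = problem_1d
        o_t = rng.random(8) + 0.1
        expected = rl_step_oracle_1d(o_t, f, h)
        assert np.allclose(rl_step(o_t, f, h), expected, atol=1e-8)

    def test_au_step_matches_loop_oracle(self, problem_1d):
        o, h, f, rng = problem_1d
        H = corr_oracle_1d(h, h)
        chi = conv_oracle_1d(corr_oracle_1d(o, o), H)
        o_t = rng.random(8) + 0.1
        K = corr_oracle_1d(o_t, H)
        K = K / K.sum()
        expected = au_step_oracle_1d(o_t, chi, K)
        assert np.allclose(au_step(o_t, chi, K), expected, atol=1e-8)

    def test_au_kernel_matches_brute_force(self, rng):
        from conftest import corr_oracle

        cur = rng.random((4, 4))
        H = rng.random((4, 4))
        K = au_kernel(cur, H)
        expected = corr_oracle(cur, H)
        assert np.allclose(K, expected / expected.sum(), atol=1e-10)
        assert np.isclose(K.sum(), 1.0, atol=1e-12)

    def test_au_kernel_with_impulse_autocorrelation(self, rng):
        """K = current ⋆ delta is the coordinate reversal of current (then
        normalized)."""
        cur = rng.random((5, 5))
        imp = np.zeros((5, 5))
        imp[2, 2] = 1.0
        K = au_kernel(cur, imp)
        assert np.allclose(K, reverse(cur) / cur.sum(), atol=1e-10)


class TestFixedPoints:
    def test_rl_impulse_kernel_is_stationary(self, problem_1d):
        o, h, f, rng = problem_1d
        imp = np.zeros(8)
        imp[4] = 1.0
        o_t = f + 0.01
        assert np.allclose(rl_step(o_t, f + 0.01, imp), o_t, atol=1e-10)

    def test_rl_flux_fixed_when_consistent(self, problem_1d):
        o, h, f, rng = problem_1d
        o_t = o + 1e-9
        f_exact = convolve(o_t, h)
        o_next = rl_step(o_t, f_exact, h)
        assert np.isclose(o_next.sum(), o_t.sum(), rtol=1e-10)

    def test_au_consistent_object_is_stationary(self, sparse_object):
        h = rasterize_psf(PsfModel(1.5, 1.0, 0.0, (31, 31)))
        o = sparse_object + 1e-9
        chi = convolve(autocorrelate(o), autocorrelate(h))
        # one iteration locks the flux; from there the shape must not move
        o1, _ = au_deconvolve(chi, h, o, 1)
        o5, _ = au_deconvolve(chi, h, o1, 4)
        assert np.allclose(o5, o1, rtol=1e-9)

    def test_au_impulse_psf_ground_truth_keeps_zero_residual(self, sparse_object):
        imp = np.zeros((31, 31))
        imp[15, 15] = 1.0
        o = sparse_object + 1e-9
        chi = autocorrelate(o)
        o1, trace = au_deconvolve(chi, imp, o, 3)
        assert trace[-1] < 1e-20

    def test_blind_joint_ground_truth_is_stationary(self, sparse_object):
        """Starting Blind-AU at the true object and true PSF, both estimates
        stay put (relative change < 1e-6 per cycle after the flux lock-in)."""
        h = rasterize_psf(PsfModel(1.5, 1.0, 0.0, (31, 31)))
        o = sparse_object + 1e-9
        chi = convolve(autocorrelate(o), autocorrelate(h))
        st1 = blind_au(chi, o, h, BlindSchedule(5, 5, 1, 1))
        st2 = blind_au(chi, st1.object_estimate, st1.psf_estimate, BlindSchedule(5, 5, 1, 1))
        rel_o = np.abs(st2.object_estimate - st1.object_estimate).max() / st1.object_estimate.max()
        rel_h = np.abs(st2.psf_estimate - st1.psf_estimate).max() / st1.psf_estimate.max()
        assert rel_o < 1e-6
        assert rel_h < 1e-6


class TestFluxAndNonnegativity:
    def test_rl_flux_and_nonnegativity_over_1000_iterations(self, sparse_object):
        h = rasterize_psf(PsfModel(1.5, 1.0, 0.0, (31, 31)))
        f = convolve(sparse_object, h) + 0.01
        o, _ = rl_deconvolve(f, h, 1)
        flux0 = o.sum()  # flux locks to sum(f) after the first step
        o, _ = rl_deconvolve(f, h, 1000, o0=o)
        assert o.min() >= 0
        assert abs(o.sum() - flux0) / flux0 < 1e-6

    def test_au_flux_and_nonnegativity_over_1000_iterations(self, sparse_object):
        h = rasterize_psf(PsfModel(1.5, 1.0, 0.0, (31, 31)))
        o_true = sparse_object + 0.01
        chi = convolve(autocorrelate(o_true), autocorrelate(h))
        o, _ = au_deconvolve(chi, h, convolve(o_true, h), 1)
        flux0 = o.sum()  # flux locks to sum(chi) after the first step
        o, _ = au_deconvolve(chi, h, o, 1000)
        assert o.min() >= 0
        assert abs(o.sum() - flux0) / flux0 < 1e-6

    def test_blind_flux_stability_over_cycles(self, sparse_object):
        h = rasterize_psf(PsfModel(1.5, 1.0, 0.0, (31, 31)))
        o_true = sparse_object + 0.01
        chi = convolve(autocorrelate(o_true), autocorrelate(h))
        o0 = convolve(o_true, h)
        h0 = rasterize_psf(PsfModel(3.0, 3.0, 0.0, (31, 31))) + 1e-12
        st = blind_au(chi, o0, h0, BlindSchedule(10, 10, 50, 1))
        fluxes = [rec["object_flux"] for rec in st.history[1:]]
        assert max(fluxes) - min(fluxes) < 1e-6 * fluxes[0]
        assert st.object_estimate.min() >= 0
        assert np.isclose(st.psf_estimate.sum(), 1.0)


class TestDrivers:
    def test_driver_single_iteration_equals_step(self, problem_1d):
        o, h, f, rng = problem_1d
        o0 = rng.random(8) + 0.1
        fast, _ = rl_deconvolve(f, h, 1, o0=o0)
        assert np.allclose(fast, rl_step(o0, f, h), atol=1e-10)

        H = autocorrelate(h)
        chi = convolve(autocorrelate(o + 1e-6), H)
        fast, _ = au_deconvolve(chi, h, o0, 1)
        assert np.allclose(fast, au_step(o0, chi, au_kernel(o0, H)), atol=1e-10)

    def test_pad_mode_driver_agrees_in_the_interior(self, sparse_object):
        """Circular and zero-padded boundary models only differ near the
        raster border; away from it the two RL solutions coincide."""
        h = rasterize_psf(PsfModel(1.5, 1.0, 0.0, (31, 31)))
        f = convolve(sparse_object, h) + 0.01
        a, _ = rl_deconvolve(f, h, 20)
        b, _ = rl_deconvolve(f, h, 20, mode="pad")
        interior = (slice(6, -6), slice(6, -6))
        assert np.allclose(a[interior], b[interior], atol=0.01 * a.max())

    def test_rl_descends_on_consistent_problem(self, sparse_object):
        h = rasterize_psf(PsfModel(1.5, 1.0, 0.0, (31, 31)))
        f = convolve(sparse_object, h) + 1e-9
        _, trace = rl_deconvolve(f, h, 100)
        assert trace[-1] < trace[0]

    def test_rl_impulse_kernel_returns_measurement(self, sparse_object):
        imp = np.zeros((31, 31))
        imp[15, 15] = 1.0
        f = sparse_object + 0.01
        o, trace = rl_deconvolve(f, imp, 5)
        assert np.allclose(o, f, rtol=1e-10)
        assert trace[-1] < 1e-20

    def test_rl_separates_blurred_two_point_object(self):
        """A Gaussian-blurred two-point object shows a single hump in the
        measurement; after 500 RL iterations the two peaks reappear with a
        deep central dip."""
        shape = (63, 63)
        o = np.zeros(shape)
        o[31, 28] = 1.0
        o[31, 34] = 1.0
        h = rasterize_psf(PsfModel(1.0, 3.0, 0.0, shape))
        f = convolve(o, h) + 1e-9
        prof_f = f[31, 25:38]
        assert np.argmax(prof_f) == len(prof_f) // 2  # unresolved hump
        rec, _ = rl_deconvolve(f, h, 500)
        prof = rec[31, 25:38]
        left, mid, right = prof[3], prof[6], prof[9]
        assert left > 0 and right > 0
        assert mid < 0.8 * min(left, right)

    def test_au_recovers_sparse_object_up_to_ambiguity(self, sparse_object):
        """Known-PSF inversion of chi: the reconstruction matches the truth
        up to cyclic translation and point reflection (NCC >= 0.95)."""
        h = rasterize_psf(PsfModel(2.0, 1.0, 0.0, (31, 31)))
        chi = convolve(autocorrelate(sparse_object), autocorrelate(h))
        o0 = np.maximum(convolve(sparse_object, h), 0) + 1e-6
        rec, trace = au_deconvolve(chi, h, o0, 8000)
        assert registered_ncc(sparse_object, rec) >= 0.95
        assert np.all(np.diff(trace[:50]) <= 1e-12)  # residual non-increasing early

    def test_blind_schedule_validation(self, sparse_object):
        with pytest.raises(ValueError):
            BlindSchedule(0, 50, 10)
        with pytest.raises(ValueError):
            BlindSchedule(50, 50, 0)
        assert BlindSchedule(50, 50, 2000).total_iterations == 2 * 10**5

    def test_blind_rejects_nonpositive_object_guess(self, sparse_object):
        chi = autocorrelate(sparse_object)
        h0 = np.full((31, 31), 1.0 / 961)
        with pytest.raises(ValueError, match="floor_zeros"):
            blind_au(chi, sparse_object, h0, BlindSchedule(1, 1, 1))
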