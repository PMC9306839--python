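import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sparse_object():
    """A small sparse nonnegative object with content away from borders."""
    rng = np.random.default_rng(7)
    o = np.zeros((31, 31))
    for _ in range(6):
        o[rng.integers(8, 24), rng.integers(8, 24)] = rng.uniform(0.5, 1.5)
    return o


# ---------------------------------------------------------------------------
# direct-sum oracles, written independently of the FFT implementation
# ---------------------------------------------------------------------------

def conv_oracle(f, g):
    """Cyclic convolution with the kernel origin at the center pixel."""
    f = np.atleast_2d(f)
    g = np.atleast_2d(g)
    n0, n1 = f.shape
    c0, c1 = n0 // 2, n1 // 2
    out = np.zeros_like(f, dtype=float)
    for i in range(n0):
        for j in range(n1):
            s = 0.0
            for y0 in range(n0):
                for y1 in range(n1):
                    s += f[y0, y1] * g[(i - y0 + c0) % n0, (j - y1 + c1) % n1]
            out[i, j] = s
    return out


def corr_oracle(f, g):
    """Cyclic cross-correlation (f ⋆ g)(x) = sum_y f(y) g(y+x), zero shift at center."""
    f = np.atleast_2d(f)
    g = np.atleast_2d(g)
    n0, n1 = f.shape
    c0, c1 = n0 // 2, n1 // 2
    out = np.zeros_like(f, dtype=float)
    for i in range(n0):
        for j in range(n1):
            s = 0.0
            for y0 in range(n0):
                for y1 in range(n1):
                    s += f[y0, y1] * g[(y0 + i - c0) % n0, (y1 + j - c1) % n1]
            out[i, j] = s
    return out


def conv_oracle_1d(f, g):
    n = len(f)
    c = n // 2
    out = np.zeros(n)
    for i in range(n):
        out[i] = sum(f[j] * g[(i - j + c) % n] for j in range(n))
    return out


def corr_oracle_1d(f, g):
    n = len(f)
    c = n // 2
    out = np.zeros(n)
    for i in range(n):
        out[i] = sum(f[j] * g[(j + i - c) % n] for j in range(n))
    return out


def reverse_oracle_1d(f):
    n = len(f)
    c = n // 2
    return np.array([f[(2 * c - x) % n] for x in range(n)])
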