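import numpy as np
import pytest

from glowmix import (
    CONTEXTS,
    MixtureDesign,
    NoiseModel,
    default_attenuation_table,
    full_bank,
)


@pytest.fixture(scope="session")
def bank():
    return full_bank()


@pytest.fixture(scope="session")
def atten_table():
    return default_attenuation_table()


@pytest.fixture
def noise_free():
    return NoiseModel(noise_free=True)


@pytest.fixture
def seeded_noise():
    return NoiseModel(seed=11)


@pytest.fixture
def invitro_design():
    return MixtureDesign.in_vitro_default("iLH2")


@pytest.fixture
def systemic():
    return CONTEXTS["systemic"]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def grid_nnls(A, v, upper, step=1e-3):
    """Brute-force nonnegative grid search for the 2-column least squares.

    Independent oracle: evaluates the residual on a regular (a, b) grid over
    [0, upper]^2 and returns the best grid point and its residual norm.
    """
    g, r = A[:, 0], A[:, 1]
    gg, rr, gr = g @ g, r @ r, g @ r
    gv, rv, vv = g @ v, r @ v, v @ v
    coords = np.arange(0.0, upper + step / 2, step)
    a = coords[:, None]
    b = coords[None, :]
    sq = a * a * gg + b * b * rr + 2 * a * b * gr - 2 * a * gv - 2 * b * rv + vv
    i, j = np.unravel_index(np.argmin(sq), sq.shape)
    best = np.array([coords[i], coords[j]])
    return best, float(np.sqrt(max(sq[i, j], 0.0)))


def grid_nnls_refined(A, v, upper, step=1e-3, stages=3, shrink=25):
    """Multi-stage exhaustive grid search: re-grids around the incumbent.

    Stays a pure enumeration (no gradient or linear-algebra solve), so it is
    an independent oracle for the nonnegative least-squares solver, but
    reaches ~step/shrink**(stages-1) resolution cheaply.
    """
    g, r = A[:, 0], A[:, 1]
    gg, rr, gr = g @ g, r @ r, g @ r
    gv, rv, vv = g @ v, r @ v, v @ v

    def search(a_lo, a_hi, b_lo, b_hi, s):
        a = np.arange(max(a_lo, 0.0), a_hi + s / 2, s)[:, None]
        b = np.arange(max(b_lo, 0.0), b_hi + s / 2, s)[None, :]
        sq = a * a * gg + b * b * rr + 2 * a * b * gr - 2 * a * gv - 2 * b * rv + vv
        i, j = np.unravel_index(np.argmin(sq), sq.shape)
        return float(a[i, 0]), float(b[0, j]), float(max(sq[i, j], 0.0))

    best_a, best_b, best_sq = search(0.0, upper, 0.0, upper, step)
    s = step
    for _ in range(stages - 1):
        s /= shrink
        best_a, best_b, best_sq = search(
            best_a - shrink * s, best_a + shrink * s,
            best_b - shrink * s, best_b + shrink * s, s,
        )
    return np.array([best_a, best_b]), float(np.sqrt(best_sq))
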