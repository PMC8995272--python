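import numpy as np
import pytest
from hypothesis import settings

from mrfviz import (
    build_dictionary,
    jiang_like_pattern,
    make_grid,
    tsne_embed,
)

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# Independent isochromat oracle: brute-force many-spin Bloch simulation of an
# unbalanced FISP train.  Spins carry uniformly distributed per-TR gradient
# dephasing angles; RF rotations are applied about the y axis (matching the
# constant 90-degree RF phase convention) and the signal is the complex mean
# transverse magnetization immediately after each pulse.  Kept free of any
# EPG machinery so it can serve as the reference for the EPG kernel.
# ---------------------------------------------------------------------------
def isochromat_fisp(t1, t2, seq, ti_ms=None, n_spins=2000):
    tr = seq.tr_ms
    theta = 2 * np.pi * (np.arange(n_spins) + 0.5) / n_spins
    M = np.zeros((n_spins, 3))
    M[:, 2] = 1.0
    e1, e2 = np.exp(-tr / t1), np.exp(-tr / t2)
    if seq.inversion:
        M[:, 2] *= -1
        ti = tr if ti_ms is None else ti_ms
        ei = np.exp(-ti / t1)
        M[:, 2] = M[:, 2] * ei + (1 - ei)
    sig = np.empty(len(seq), dtype=complex)
    for i, adeg in enumerate(seq.angles):
        a = np.deg2rad(adeg)
        x = M[:, 0] * np.cos(a) + M[:, 2] * np.sin(a)
        z = -M[:, 0] * np.sin(a) + M[:, 2] * np.cos(a)
        M[:, 0], M[:, 2] = x, z
        sig[i] = np.mean(M[:, 0] + 1j * M[:, 1])
        M[:, 0] *= e2
        M[:, 1] *= e2
        M[:, 2] = M[:, 2] * e1 + (1 - e1)
        c, s = np.cos(theta), np.sin(theta)
        x = M[:, 0] * c - M[:, 1] * s
        y = M[:, 0] * s + M[:, 1] * c
        M[:, 0], M[:, 1] = x, y
    return sig


@pytest.fixture(scope="session")
def isochromat_oracle():
    return isochromat_fisp


@pytest.fixture(scope="session")
def full_scale_grid():
    """The full-scale relaxation grid: T1 20-2000/30 ms, T2 10-300/10 ms, T1 > T2."""
    return make_grid(20, 2000, 30, 10, 300, 10)


@pytest.fixture(scope="session")
def small_grid():
    """A coarse grid (38 entries) for fast unit tests."""
    return make_grid(100, 1900, 200, 20, 140, 40)


@pytest.fixture(scope="session")
def short_seq():
    return jiang_like_pattern(150, seed=0)


@pytest.fixture(scope="session")
def small_dict(small_grid, short_seq):
    return build_dictionary(small_grid, short_seq)


@pytest.fixture(scope="session")
def full_scale_dict(full_scale_grid):
    """Full-scale dictionary (1855 x 1000) for the smooth-train fixture."""
    return build_dictionary(full_scale_grid, jiang_like_pattern(1000, seed=0))


@pytest.fixture(scope="session")
def full_scale_tsne_e1(full_scale_dict):
    """Reference 2D t-SNE run (seed 0) on the full-scale dictionary."""
    return tsne_embed(full_scale_dict, n_dim=2, seed=0)
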