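import itertools

import numpy as np
import pytest

from gimbrain.ising import CouplingMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def pair_coupling():
    """Two spins with unit coupling."""
    return CouplingMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]))


@pytest.fixture
def uniform5():
    """Five uniformly coupled spins, J = 0.2."""
    J = np.full((5, 5), 0.2)
    np.fill_diagonal(J, 0.0)
    return CouplingMatrix(J)


def exact_moments(coupling: CouplingMatrix, T: float) -> dict:
    """Boltzmann-enumeration oracle for small systems (N <= ~12).

    Enumerates every spin configuration, weights by exp(-E/T) with the
    double-sum energy E = -s^T J s, and returns exact magnetization
    moments and susceptibility under the |m| convention.
    """
    n = coupling.n_regions
    states = np.array(list(itertools.product([-1.0, 1.0], repeat=n)))
    E = -np.einsum("si,ij,sj->s", states, coupling.J, states)
    w = np.exp(-(E - E.min()) / T)
    w /= w.sum()
    m = states.mean(axis=1)
    m2 = float(w @ m**2)
    mabs = float(w @ np.abs(m))
    return {
        "m2": m2,
        "mabs": mabs,
        "chi": n * (m2 - mabs**2) / T,
        "probs": w,
        "states": states,
        "energies": E,
    }
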