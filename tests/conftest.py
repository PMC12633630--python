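import itertools

import numpy as np
import pytest

from fitbench import (FitnessLandscape, SimulationConfig, sample_landscape,
                      run_replicate)
from fitbench.freqstats import MomentSet


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_landscape():
    """L=2 hand-checkable landscape: f = (0.1, -0.2), f01 = 0.05."""
    fij = np.zeros((2, 2))
    fij[0, 1] = 0.05
    return FitnessLandscape(2, 0.0, np.array([0.1, -0.2]), fij)


@pytest.fixture
def random_landscape():
    return sample_landscape(8, 0.05, 0.02, seed=99)


@pytest.fixture
def tiny_trajectory():
    """One fast replicate: N=100, L=6, T=5."""
    fl = sample_landscape(6, 0.05, 0.0, seed=3)
    cfg = SimulationConfig(N=100, L=6, T=5, r=0.5, mu=0.01, seed=11)
    return run_replicate(fl, cfg, 0), fl


def exact_ising_moments(h, J):
    """Brute-force Boltzmann moments of a small Ising model.

    Enumerates all 2^L spin states of P(s) ∝ exp(h·s + sum_{i<j} J_ij s_i s_j)
    and returns a MomentSet with the exact chi_i / chi_ij (lam = 0).
    Independent oracle for the naive-mean-field inversion.
    """
    h = np.asarray(h, dtype=float)
    L = h.size
    J = np.asarray(J, dtype=float)
    states = np.array(list(itertools.product([-1, 1], repeat=L)), dtype=float)
    energy = states @ h + 0.5 * np.einsum("ni,ij,nj->n", states, J, states)
    w = np.exp(energy - energy.max())
    p = w / w.sum()
    chi = states.T @ p
    second = (states * p[:, None]).T @ states
    chi_ij = second - np.outer(chi, chi)
    np.fill_diagonal(chi_ij, 1.0 - chi ** 2)
    m = (chi + 1) / 2
    m_ij = (second + chi[:, None] + chi[None, :] + 1) / 4
    np.fill_diagonal(m_ij, m)
    return MomentSet(0, chi, chi_ij, m, m_ij, n_samples=np.inf, lam=0.0)


def momentset_from_freqs(m, generation=0, lam=0.0):
    """MomentSet for independent loci at exact frequencies m (m_ij = m_i m_j)."""
    m = np.asarray(m, dtype=float)
    chi = 2 * m - 1
    m_ij = np.outer(m, m)
    np.fill_diagonal(m_ij, m)
    chi_ij = np.zeros((m.size, m.size))
    np.fill_diagonal(chi_ij, 1 - chi ** 2)
    return MomentSet(generation, chi, chi_ij, m, m_ij, n_samples=np.inf, lam=lam)
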