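"""Single- and pair-locus statistics from trajectory samples.

Two equivalent conventions are used throughout the package:

* spin convention: magnetizations chi_i = <s_i> and connected correlations
  chi_ij = <s_i s_j> - <s_i><s_j> for spins s in {-1, +1};
* frequency convention: allele frequencies m_i = P(s_i = +1) and pair
  frequencies m_ij = P(s_i = +1, s_j = +1).

They are linked exactly by chi_i = 2 m_i - 1 and chi_ij = 4 (m_ij - m_i m_j).

A pseudocount ``lam`` regularizes the estimates: each pair's four joint-state
counts receive lam/4 and each single-locus state count lam/2 before
normalization.  This equals mixing the empirical distribution with the
uniform independent one with weight lam / (n + lam), which keeps |chi_i| < 1
(finite atanh) and the correlation matrix positive definite — both required
by the naive-mean-field inversion downstream.  Default lam = 0.5 per table
(Jeffreys-like).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .wfsim import Trajectory

DEFAULT_LAMBDA = 0.5


@dataclass(frozen=True)
class MomentSet:
    """Locus statistics at one generation (possibly pooled over replicates)."""

    generation: int
    chi_i: np.ndarray    # (L,) magnetizations, in (-1, 1) for lam > 0
    chi_ij: np.ndarray   # (L, L) connected correlations; diagonal 1 - chi_i^2
    m_i: np.ndarray      # (L,) +1-allele frequencies
    m_ij: np.ndarray     # (L, L) joint (+1, +1) frequencies; diagonal m_i
    n_samples: float     # genomes counted (without pseudocount mass)
    lam: float

    @property
    def L(self) -> int:
        return int(self.chi_i.size)

    def correlation_matrix(self) -> np.ndarray:
        """C with C_ij = chi_ij off-diagonal and C_ii = 1 - chi_i^2."""
        return self.chi_ij.copy()

    def monomorphic_sites(self, tol: float = 0.0) -> np.ndarray:
        """Sites whose raw sample was monomorphic (|chi| at the pseudocount cap)."""
        cap = 1.0 - self.lam / (self.n_samples + self.lam) if self.lam > 0 else 1.0
        return np.abs(self.chi_i) >= cap - tol


def spins_to_binary(X: np.ndarray) -> np.ndarray:
    """Spin {-1,+1} -> binary {0,1} via x = (s + 1) / 2."""
    X = np.asarray(X)
    if not np.all(np.abs(X) == 1):
        raise ValueError("spin entries must be +-1")
    return ((X + 1) // 2).astype(X.dtype)


def binary_to_spins(X: np.ndarray) -> np.ndarray:
    """Binary {0,1} -> spin {-1,+1} via s = 2x - 1."""
    X = np.asarray(X)
    if not np.all((X == 0) | (X == 1)):
        raise ValueError("binary entries must be 0/1")
    return (2 * X - 1).astype(X.dtype)


def raw_counts(genotypes: np.ndarray, counts: np.ndarray):
    """Weighted sufficient statistics of a unique-genotype sample.

    Returns ``(n, n_plus, n_pp)``: total genome count, per-locus +1-allele
    counts, and the pairwise (+1, +1) count matrix (diagonal = n_plus).
    These add across pooled samples, which makes cumulative pooling cheap.
    """
    X = np.asarray(genotypes, dtype=float)
    w = np.asarray(counts, dtype=float)
    plus = (X + 1) / 2
    n_plus = plus.T @ w
    n_pp = (plus * w[:, None]).T @ plus
    return float(w.sum()), n_plus, n_pp


def moments_from_counts(n: float, n_plus: np.ndarray, n_pp: np.ndarray,
                        lam: float = DEFAULT_LAMBDA,
                        generation: int = 0) -> MomentSet:
    """Pseudocounted moments from additive sufficient statistics."""
    if lam < 0:
        raise ValueError("lam must be non-negative")
    m_i = (n_plus + lam / 2) / (n + lam)
    m_ij = (n_pp + lam / 4) / (n + lam)
    np.fill_diagonal(m_ij, m_i)
    chi_i = 2.0 * m_i - 1.0
    chi_ij = 4.0 * (m_ij - np.outer(m_i, m_i))
    np.fill_diagonal(chi_ij, 1.0 - chi_i ** 2)
    return MomentSet(generation, chi_i, chi_ij, m_i, m_ij, float(n), float(lam))


def moments_from_sample(genotypes: np.ndarray, counts: np.ndarray,
                        lam: float = DEFAULT_LAMBDA,
                        generation: int = 0) -> MomentSet:
    """Count-weighted moments of a unique-genotype sample with pseudocount."""
    n, n_plus, n_pp = raw_counts(genotypes, counts)
    return moments_from_counts(n, n_plus, n_pp, lam, generation)


def moments(traj: Trajectory, generation: int,
            lam: float = DEFAULT_LAMBDA) -> MomentSet:
    """Moments of a single trajectory at one recorded generation."""
    rec = traj.record_at(generation)
    return moments_from_sample(rec.genotypes, rec.counts, lam, generation)


def pooled_moments(trajs: list[Trajectory], generation: int,
                   lam: float = DEFAULT_LAMBDA,
                   cumulative: bool = False) -> MomentSet:
    """Moments pooled across replicates.

    ``cumulative=True`` pools all samples from generations 0..generation of
    every replicate (the accumulation rule used for coupling estimation);
    ``cumulative=False`` pools only the requested generation.
    """
    _check_shared_config(trajs)
    gs, cs = [], []
    for tr in trajs:
        for rec in tr.records:
            if rec.generation == generation or (cumulative and rec.generation <= generation):
                gs.append(rec.genotypes)
                cs.append(rec.counts)
    if not gs:
        raise KeyError(f"generation {generation} not recorded in any trajectory")
    return moments_from_sample(np.vstack(gs), np.concatenate(cs), lam, generation)


def frequency_trajectory(traj: Trajectory,
                         lam: float = DEFAULT_LAMBDA) -> list[MomentSet]:
    """One MomentSet per recorded generation, in time order."""
    return [moments_from_sample(r.genotypes, r.counts, lam, r.generation)
            for r in traj.records]


def pooled_frequency_trajectory(trajs: list[Trajectory],
                                lam: float = DEFAULT_LAMBDA,
                                cumulative: bool = False) -> list[MomentSet]:
    """Per-generation series pooled across replicates (sharing a time grid).

    With ``cumulative=True`` entry k pools every sample up to and including
    generation k; sufficient statistics are accumulated incrementally so the
    cost is linear in the number of recorded generations.
    """
    _check_shared_config(trajs)
    gens = trajs[0].generations
    L = trajs[0].config.L
    out = []
    acc_n, acc_plus, acc_pp = 0.0, np.zeros(L), np.zeros((L, L))
    for g in gens:
        n, n_plus, n_pp = 0.0, np.zeros(L), np.zeros((L, L))
        for tr in trajs:
            rec = tr.record_at(g)
            dn, dplus, dpp = raw_counts(rec.genotypes, rec.counts)
            n += dn
            n_plus += dplus
            n_pp += dpp
        if cumulative:
            acc_n += n
            acc_plus += n_plus
            acc_pp += n_pp
            out.append(moments_from_counts(acc_n, acc_plus.copy(), acc_pp.copy(), lam, g))
        else:
            out.append(moments_from_counts(n, n_plus, n_pp, lam, g))
    return out


def sampling_intervals(series: list[MomentSet]) -> np.ndarray:
    """Delta t_k between consecutive entries of a moment series."""
    gens = np.array([ms.generation for ms in series])
    return np.diff(gens)


def export_moments(series: list[MomentSet], path) -> None:
    """Audit export: long format (generation, i, j, statistic, value)."""
    with open(path, "w") as fh:
        fh.write("generation\ti\tj\tstatistic\tvalue\n")
        for ms in series:
            for i in range(ms.L):
                fh.write(f"{ms.generation}\t{i}\t{i}\tm_i\t{ms.m_i[i]:.17g}\n")
                fh.write(f"{ms.generation}\t{i}\t{i}\tchi_i\t{ms.chi_i[i]:.17g}\n")
            for i in range(ms.L):
                for j in range(i + 1, ms.L):
                    fh.write(f"{ms.generation}\t{i}\t{j}\tm_ij\t{ms.m_ij[i, j]:.17g}\n")
                    fh.write(f"{ms.generation}\t{i}\t{j}\tchi_ij\t{ms.chi_ij[i, j]:.17g}\n")


def _check_shared_config(trajs: list[Trajectory]) -> None:
    if not trajs:
        raise ValueError("no trajectories supplied")
    cfg0 = trajs[0].config
    for tr in trajs[1:]:
        if tr.config != cfg0:
            raise ValueError("all trajectories must share a SimulationConfig")
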