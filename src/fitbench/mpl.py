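"""Marginal path likelihood (MPL) inference of additive selection.

MPL models allele-frequency trajectories in the Wright-Fisher diffusion
limit.  Maximizing the likelihood of the observed frequency path with a
Gaussian prior of width gamma yields a ridge-regularized linear solve

    ( sum_k dt_k D(t_k) + gamma I ) s = m(t_K) - m(t_0) - mu sum_k dt_k (1 - 2 m(t_k)),

where D is the single-generation diffusion matrix in the 0/1 frequency
convention (diagonal m_i (1 - m_i), off-diagonal m_ij - m_i m_j), the
right-hand side is the net frequency change minus the integrated mutational
flux, and the sum uses a left-endpoint rule over each sampling interval.

Convention bridge: the solve is performed in the 0/1 allele convention; the
quadratic landscape is written over spins s in {-1, +1}, where changing one
allele changes log-fitness by 2 f_i.  Hence f_i* = s_i / 2.  The model is
purely additive — epistatic ground truth acts as a confounder, never as an
estimation target.

Replicates are pooled by summing sufficient statistics (independent paths,
additive log-likelihoods).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .freqstats import (DEFAULT_LAMBDA, MomentSet, frequency_trajectory,
                        sampling_intervals)
from .landscape import InferredLandscape
from .wfsim import Trajectory

DEFAULT_GAMMA = 0.1


@dataclass(frozen=True)
class MplSufficientStatistics:
    """Everything the MPL solve needs, additive across replicates."""

    cint: np.ndarray       # (L, L) integrated diffusion matrix
    dm: np.ndarray         # (L,) net frequency change over the interval
    mut_flux: np.ndarray   # (L,) integrated mutational flux
    gamma: float
    time_grid: tuple       # recorded generations

    def __add__(self, other: "MplSufficientStatistics") -> "MplSufficientStatistics":
        if self.gamma != other.gamma:
            raise ValueError("cannot pool statistics with different gamma")
        return MplSufficientStatistics(self.cint + other.cint,
                                       self.dm + other.dm,
                                       self.mut_flux + other.mut_flux,
                                       self.gamma,
                                       self.time_grid)


def diffusion_matrix(ms: MomentSet) -> np.ndarray:
    """Single-generation diffusion matrix in the 0/1 convention."""
    D = ms.m_ij - np.outer(ms.m_i, ms.m_i)
    np.fill_diagonal(D, ms.m_i * (1.0 - ms.m_i))
    return D


def accumulate_statistics(series: list[MomentSet], mu: float, gamma: float,
                          endpoint_series: list[MomentSet] | None = None,
                          quadrature: str = "left") -> MplSufficientStatistics:
    """Build the sufficient statistics from a frequency time series.

    The diffusion matrix and the mutational flux are integrated with a
    left-endpoint rule over each interval (``quadrature="trapezoid"``
    averages endpoints instead).  ``endpoint_series``, when given, supplies
    the raw (un-pseudocounted) frequencies used for the net change ``dm``;
    the pseudocounted ``series`` regularizes the diffusion matrix.
    """
    if len(series) < 2:
        raise ValueError("need at least two time points")
    if quadrature not in ("left", "trapezoid"):
        raise ValueError("quadrature must be 'left' or 'trapezoid'")
    dts = sampling_intervals(series)
    L = series[0].L
    cint = np.zeros((L, L))
    mut_flux = np.zeros(L)
    for k, dt in enumerate(dts):
        if quadrature == "left":
            D = diffusion_matrix(series[k])
            flux = 1.0 - 2.0 * series[k].m_i
        else:
            D = (diffusion_matrix(series[k]) + diffusion_matrix(series[k + 1])) / 2
            flux = 1.0 - (series[k].m_i + series[k + 1].m_i)
        cint += dt * D
        mut_flux += mu * dt * flux
    ends = endpoint_series if endpoint_series is not None else series
    dm = ends[-1].m_i - ends[0].m_i
    grid = tuple(ms.generation for ms in series)
    return MplSufficientStatistics(cint, dm, mut_flux, float(gamma), grid)


def solve_mpl(stats: MplSufficientStatistics) -> np.ndarray:
    """Ridge solve for the selection coefficients, returned as spin-convention f_i*.

    Solves (Cint + gamma I) s = dm - mut_flux in the 0/1 convention and
    returns f_i* = s / 2.
    """
    L = stats.dm.size
    A = stats.cint + stats.gamma * np.eye(L)
    b = stats.dm - stats.mut_flux
    try:
        s = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "integrated covariance is singular; use gamma > 0") from exc
    return s / 2.0


def infer_mpl(trajs: list[Trajectory] | Trajectory,
              mu: float | None = None,
              gamma: float = DEFAULT_GAMMA,
              lam: float = DEFAULT_LAMBDA,
              quadrature: str = "left") -> InferredLandscape:
    """End-to-end MPL inference, pooling replicates by summed statistics."""
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    if not trajs:
        raise ValueError("no trajectories supplied")
    mu = trajs[0].config.mu if mu is None else mu
    total = None
    for tr in trajs:
        smooth = frequency_trajectory(tr, lam)
        raw = frequency_trajectory(tr, 0.0)
        stats = accumulate_statistics(smooth, mu, gamma, endpoint_series=raw,
                                      quadrature=quadrature)
        total = stats if total is None else total + stats
    fi = solve_mpl(total)
    return InferredLandscape(fi, None, "mpl",
                             {"gamma": gamma, "mu": mu, "lam": lam,
                              "quadrature": quadrature,
                              "n_replicates": len(trajs)},
                             {"replicates": [tr.replicate_id for tr in trajs]})
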