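"""Quadratic fitness landscapes over binary (spin) genomes.

A genotype is a length-``L`` vector of spins ``s_i in {-1, +1}``.  Log-fitness
is quadratic,

    F(g) = f0 + sum_i f_i s_i + sum_{i<j} f_ij s_i s_j,

with additive effects ``f_i`` and pairwise epistatic effects ``f_ij``.  The
offset ``f0`` shifts every genotype equally; reproductive success depends only
on relative fitness, so ``f0`` is carried through but is never an inference
target.

Epistatic coefficients are stored strictly upper-triangular so that the
symmetry ``f_ij == f_ji`` and the zero diagonal are structural rather than
conventional.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np


class FitnessComponents(NamedTuple):
    """Exact decomposition ``total = f0 + additive + epistatic``."""

    total: float
    additive: float
    epistatic: float


def _validate_spins(s: np.ndarray) -> np.ndarray:
    s = np.asarray(s)
    if not np.all(np.abs(s) == 1):
        raise ValueError("genotype entries must be exactly -1 or +1")
    return s


@dataclass(frozen=True)
class FitnessLandscape:
    """Ground-truth parameters of a quadratic log-fitness function.

    Parameters
    ----------
    L : int
        Number of loci.
    f0 : float
        Constant offset (log-fitness units).
    fi : ndarray, shape (L,)
        Additive effects per locus.
    fij : ndarray, shape (L, L)
        Pairwise epistatic effects; strictly upper-triangular storage
        (zero on and below the diagonal).  Use :meth:`coupling` or
        :meth:`fij_symmetric` for symmetric access.
    meta : dict
        Provenance: sampling standard deviations and seed.
    """

    L: int
    f0: float
    fi: np.ndarray
    fij: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        fi = np.asarray(self.fi, dtype=float)
        fij = np.asarray(self.fij, dtype=float)
        if self.L < 1:
            raise ValueError("L must be positive")
        if fi.shape != (self.L,):
            raise ValueError(f"fi must have shape ({self.L},), got {fi.shape}")
        if fij.shape != (self.L, self.L):
            raise ValueError(f"fij must have shape ({self.L}, {self.L})")
        if np.any(np.tril(fij) != 0.0):
            raise ValueError("fij must be strictly upper-triangular")
        object.__setattr__(self, "fi", fi)
        object.__setattr__(self, "fij", fij)

    def coupling(self, i: int, j: int) -> float:
        """Symmetric accessor: value for (i, j) equals value for (j, i)."""
        if i == j:
            return 0.0
        i, j = (i, j) if i < j else (j, i)
        return float(self.fij[i, j])

    def fij_symmetric(self) -> np.ndarray:
        """Full symmetric L x L matrix with zero diagonal."""
        return self.fij + self.fij.T

    def with_offset(self, f0: float) -> "FitnessLandscape":
        return FitnessLandscape(self.L, f0, self.fi.copy(), self.fij.copy(), dict(self.meta))


@dataclass(frozen=True)
class InferredLandscape:
    """Estimated fitness parameters with method provenance.

    ``fij_star`` is present only when the method infers epistasis (tQLE in
    full mode); MPL and additive-only tQLE leave it ``None``, and genotype
    fitness predictions then use the additive term alone.
    """

    fi_star: np.ndarray
    fij_star: np.ndarray | None
    method: str
    hyperparams: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        fi = np.asarray(self.fi_star, dtype=float)
        object.__setattr__(self, "fi_star", fi)
        if self.fij_star is not None:
            fij = np.asarray(self.fij_star, dtype=float)
            if fij.shape != (fi.size, fi.size):
                raise ValueError("fij_star must be L x L")
            if np.any(np.tril(fij) != 0.0):
                raise ValueError("fij_star must be strictly upper-triangular")
            object.__setattr__(self, "fij_star", fij)

    @property
    def L(self) -> int:
        return int(self.fi_star.size)

    def as_landscape(self) -> FitnessLandscape:
        """View the estimate as a landscape with f0 = 0 (for fitness prediction)."""
        fij = self.fij_star if self.fij_star is not None else np.zeros((self.L, self.L))
        return FitnessLandscape(self.L, 0.0, self.fi_star, fij,
                                {"method": self.method, **self.hyperparams})


def sample_landscape(L: int, sigma_fi: float, sigma_fij: float,
                     seed: int | np.random.SeedSequence) -> FitnessLandscape:
    """Draw a random quadratic landscape.

    Additive effects are i.i.d. Normal(0, sigma_fi); each epistatic pair
    (i < j) is i.i.d. Normal(0, sigma_fij).  ``f0 = 0``.  With both sigmas
    zero all coefficients are exactly zero.
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    if sigma_fi < 0 or sigma_fij < 0:
        raise ValueError("standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    fi = rng.normal(0.0, sigma_fi, size=L) if sigma_fi > 0 else np.zeros(L)
    fij = np.zeros((L, L))
    iu = np.triu_indices(L, k=1)
    if sigma_fij > 0:
        fij[iu] = rng.normal(0.0, sigma_fij, size=iu[0].size)
    meta = {"sigma_fi": float(sigma_fi), "sigma_fij": float(sigma_fij),
            "seed": seed if isinstance(seed, int) else repr(seed)}
    return FitnessLandscape(L, 0.0, fi, fij, meta)


def fitness_of(g: np.ndarray, fl: FitnessLandscape) -> FitnessComponents:
    """Evaluate F(g) and its exact additive/epistatic decomposition."""
    s = _validate_spins(g).astype(float)
    if s.shape != (fl.L,):
        raise ValueError(f"genotype length {s.shape} does not match L={fl.L}")
    additive = float(fl.fi @ s)
    epistatic = float(s @ fl.fij @ s)  # upper-triangular: each pair counted once
    return FitnessComponents(fl.f0 + additive + epistatic, additive, epistatic)


def fitness_of_many(X: np.ndarray, fl: FitnessLandscape):
    """Vectorized fitness for a stack of genotypes.

    Parameters
    ----------
    X : ndarray, shape (n, L)
        Spin matrix, entries +-1.

    Returns
    -------
    (total, additive, epistatic) : arrays of shape (n,)
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != fl.L:
        raise ValueError(f"X must be (n, {fl.L})")
    additive = X @ fl.fi
    epistatic = np.einsum("ni,ij,nj->n", X, fl.fij, X)
    return fl.f0 + additive + epistatic, additive, epistatic


def reproductive_weight(g: np.ndarray, fl: FitnessLandscape) -> float:
    """Malthusian sampling weight exp(F(g)).

    Strictly positive and monotone in F; a shift of f0 multiplies all weights
    by a common factor and so leaves selection outcomes unchanged.
    """
    return float(np.exp(fitness_of(g, fl).total))


# ---------------------------------------------------------------------------
# Landscape file format: JSON with fij as sparse (i, j, value) triplets, i < j.
# ---------------------------------------------------------------------------

def save_landscape(fl: FitnessLandscape | InferredLandscape, path) -> None:
    if isinstance(fl, InferredLandscape):
        doc = {
            "L": fl.L,
            "f0": 0.0,
            "fi": fl.fi_star.tolist(),
            "fij": _triplets(fl.fij_star) if fl.fij_star is not None else None,
            "meta": {"method": fl.method, "hyperparams": _jsonable(fl.hyperparams),
                     "provenance": _jsonable(fl.provenance)},
        }
    else:
        doc = {"L": fl.L, "f0": fl.f0, "fi": fl.fi.tolist(),
               "fij": _triplets(fl.fij), "meta": _jsonable(fl.meta)}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_landscape(path) -> FitnessLandscape:
    with open(path) as fh:
        doc = json.load(fh)
    L = int(doc["L"])
    fij = np.zeros((L, L))
    for i, j, v in (doc.get("fij") or []):
        if not (0 <= i < j < L):
            raise ValueError(f"invalid fij index pair ({i}, {j})")
        fij[i, j] = v
    return FitnessLandscape(L, float(doc.get("f0", 0.0)),
                            np.asarray(doc["fi"], dtype=float), fij,
                            doc.get("meta", {}))


def _triplets(fij: np.ndarray) -> list:
    iu = np.triu_indices(fij.shape[0], k=1)
    return [[int(i), int(j), float(fij[i, j])]
            for i, j in zip(*iu) if fij[i, j] != 0.0]


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, np.generic):
            v = v.item()
        elif isinstance(v, np.ndarray):
            v = v.tolist()
        elif isinstance(v, dict):
            v = _jsonable(v)
        out[k] = v
    return out
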