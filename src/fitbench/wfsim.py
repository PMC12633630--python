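"""Discrete-generation haploid Wright-Fisher simulator.

Each generation applies, in a fixed order:

1. selection + drift: N offspring are drawn by multinomial sampling with
   probabilities proportional to exp(F(g));
2. recombination: each offspring outcrosses with probability ``r``; an
   outcrossed offspring is replaced by a recombinant of itself and a second
   parent drawn uniformly from the post-selection pool, inheriting each locus
   from either parent independently with probability 1/2 (free recombination);
3. mutation: every site of every individual flips sign independently with
   probability ``mu``.

``r`` is the per-offspring outcrossing probability; under free recombination
the probability that recombination separates a given locus pair is
``c_ij = 1/2`` for all pairs, so the effective pairwise decay rate is
``r * c``.  The event order within a generation is centralized here; any
fixed order differs only at O(mu, 1/N) per generation.

Populations are evolved as dense (N, L) int8 spin matrices and compressed to
unique-genotype counts when recorded into a :class:`Trajectory`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .landscape import FitnessLandscape, fitness_of_many

INIT_MODES = ("uniform_random", "monomorphic", "given_frequencies")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated evolution run.

    Defaults correspond to the benchmark's standard conditions: N=1000
    individuals, L=25 loci, T=30 generations, strong recombination r=0.5,
    mutation rate mu=0.01 per site per generation, whole-population sampling.
    """

    N: int = 1000
    L: int = 25
    T: int = 30
    r: float = 0.5
    mu: float = 0.01
    n_replicates: int = 1
    seed: int = 0
    init_mode: str = "uniform_random"
    init_frequencies: tuple | None = None
    sample_fraction: float = 1.0
    c: float = 0.5  # pairwise separation probability under free recombination

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.T < 0:
            raise ValueError("T must be >= 0")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("r must be in [0, 1]")
        if not 0.0 <= self.mu <= 0.5:
            raise ValueError("mu must be in [0, 0.5]")
        if not 0.0 < self.sample_fraction <= 1.0:
            raise ValueError("sample_fraction must be in (0, 1]")
        if not 0.0 < self.c <= 0.5:
            raise ValueError("c must be in (0, 1/2]")
        if self.init_mode not in INIT_MODES:
            raise ValueError(f"init_mode must be one of {INIT_MODES}")
        if self.init_mode == "given_frequencies":
            f = np.asarray(self.init_frequencies, dtype=float)
            if f.shape != (self.L,) or np.any(f < 0) or np.any(f > 1):
                raise ValueError("init_frequencies must be L values in [0, 1]")


@dataclass(frozen=True)
class TrajectoryRecord:
    """Sample at one generation: unique genotypes and their counts."""

    generation: int
    genotypes: np.ndarray  # (n_unique, L) int8, entries +-1
    counts: np.ndarray     # (n_unique,) positive ints

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())

    def expand(self) -> np.ndarray:
        """Individual-level (n_samples, L) matrix, counts expanded."""
        return np.repeat(self.genotypes, self.counts, axis=0)


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped genotype samples from one simulation replicate."""

    replicate_id: int
    config: SimulationConfig
    landscape_ref: str
    records: tuple[TrajectoryRecord, ...]

    def __post_init__(self) -> None:
        gens = [r.generation for r in self.records]
        if gens != sorted(set(gens)) or (gens and gens[0] != 0):
            raise ValueError("generations must be strictly increasing from 0")

    @property
    def generations(self) -> list[int]:
        return [r.generation for r in self.records]

    def record_at(self, generation: int) -> TrajectoryRecord:
        for r in self.records:
            if r.generation == generation:
                return r
        raise KeyError(f"generation {generation} not recorded")

    def thinned(self, keep: Sequence[int]) -> "Trajectory":
        """Trajectory restricted to a subset of recorded generations."""
        recs = tuple(r for r in self.records if r.generation in set(keep))
        return replace(self, records=recs)


def replicate_rng(seed: int, replicate_id: int) -> np.random.Generator:
    """Independent, individually reproducible stream for one replicate.

    Key derivation: SeedSequence spawned from (seed, (0, replicate_id)), so
    replicate k's stream does not depend on how many replicates are run.
    The (1,) spawn key is reserved for landscape sampling at the experiment
    level, keeping all streams disjoint under one root seed.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(0, replicate_id)))


def init_population(cfg: SimulationConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Initial (N, L) spin matrix according to ``cfg.init_mode``."""
    if cfg.init_mode == "monomorphic":
        return -np.ones((cfg.N, cfg.L), dtype=np.int8)
    if cfg.init_mode == "uniform_random":
        freqs = np.full(cfg.L, 0.5)
    else:
        freqs = np.asarray(cfg.init_frequencies, dtype=float)
    draws = rng.random((cfg.N, cfg.L)) < freqs
    return np.where(draws, 1, -1).astype(np.int8)


def step(pop: np.ndarray, fl: FitnessLandscape, cfg: SimulationConfig,
         rng: np.random.Generator) -> np.ndarray:
    """Advance one generation: selection+drift, recombination, mutation."""
    n = pop.shape[0]
    if n == 0:
        raise RuntimeError("population is empty")
    total, _, _ = fitness_of_many(pop, fl)
    # subtract max before exponentiating: weights invariant to f0 up to a
    # common factor, and this keeps exp() in range for any landscape draw
    w = np.exp(total - total.max())
    p = w / w.sum()
    parents = rng.choice(n, size=cfg.N, p=p)
    off = pop[parents].copy()

    if cfg.r > 0:
        cross = rng.random(cfg.N) < cfg.r
        k = int(cross.sum())
        if k:
            # second parent uniform from the post-selection pool itself
            mates = off[rng.integers(0, cfg.N, size=k)]
            take_mate = rng.random((k, cfg.L)) < 0.5
            off[cross] = np.where(take_mate, mates, off[cross])

    if cfg.mu > 0:
        flips = rng.random((cfg.N, cfg.L)) < cfg.mu
        off[flips] *= -1
    return off


def _compress(pop: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, counts = np.unique(pop, axis=0, return_counts=True)
    return uniq.astype(np.int8), counts


def _record(pop: np.ndarray, generation: int, cfg: SimulationConfig,
            rng: np.random.Generator) -> TrajectoryRecord:
    if cfg.sample_fraction < 1.0:
        k = round(cfg.N * cfg.sample_fraction)
        idx = rng.choice(pop.shape[0], size=k, replace=False)
        pop = pop[idx]
    uniq, counts = _compress(pop)
    return TrajectoryRecord(generation, uniq, counts)


def run_replicate(fl: FitnessLandscape, cfg: SimulationConfig,
                  replicate_id: int = 0) -> Trajectory:
    """Simulate one replicate: record generation 0 then T stepped generations."""
    rng = replicate_rng(cfg.seed, replicate_id)
    pop = init_population(cfg, rng)
    records = [_record(pop, 0, cfg, rng)]
    for gen in range(1, cfg.T + 1):
        pop = step(pop, fl, cfg, rng)
        records.append(_record(pop, gen, cfg, rng))
    ref = f"sigma_fi={fl.meta.get('sigma_fi')},sigma_fij={fl.meta.get('sigma_fij')}"
    return Trajectory(replicate_id, cfg, ref, tuple(records))


def simulate_replicates(fl: FitnessLandscape,
                        cfg: SimulationConfig) -> list[Trajectory]:
    """Run ``cfg.n_replicates`` independent replicates of the same landscape."""
    return [run_replicate(fl, cfg, k) for k in range(cfg.n_replicates)]


# ---------------------------------------------------------------------------
# Trajectory file formats.
# Dialect A: delimited table (replicate, generation, genotype string, count).
# Dialect B: FASTA, one record per unique genotype per generation, header
#            >rep<k>|t<G>|n<count>, alphabet {A, T} with -1 -> A, +1 -> T.
# ---------------------------------------------------------------------------

_SPIN_CHARS = {"+": 1, "-": -1, "1": 1, "0": -1}


def save_trajectory_table(trajs: Iterable[Trajectory], path,
                          alphabet: str = "+-") -> None:
    if alphabet not in ("+-", "01"):
        raise ValueError("alphabet must be '+-' or '01'")
    plus, minus = ("+", "-") if alphabet == "+-" else ("1", "0")
    with open(path, "w") as fh:
        fh.write(f"# alphabet={alphabet} (plus-allele first)\n")
        fh.write("replicate\tgeneration\tgenotype\tcount\n")
        for tr in trajs:
            for rec in tr.records:
                for g, c in zip(rec.genotypes, rec.counts):
                    seq = "".join(plus if s == 1 else minus for s in g)
                    fh.write(f"{tr.replicate_id}\t{rec.generation}\t{seq}\t{c}\n")


def load_trajectory_table(path, config: SimulationConfig | None = None) -> list[Trajectory]:
    rows: dict[int, dict[int, list]] = {}
    L = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("replicate"):
                continue
            rep, gen, seq, count = line.split("\t")
            g = np.array([_SPIN_CHARS[ch] for ch in seq], dtype=np.int8)
            L = len(g)
            rows.setdefault(int(rep), {}).setdefault(int(gen), []).append((g, int(count)))
    return _assemble(rows, L, config)


def save_trajectory_fasta(trajs: Iterable[Trajectory], path) -> None:
    with open(path, "w") as fh:
        fh.write("; spin mapping: -1 -> A, +1 -> T\n")
        for tr in trajs:
            for rec in tr.records:
                for g, c in zip(rec.genotypes, rec.counts):
                    seq = "".join("T" if s == 1 else "A" for s in g)
                    fh.write(f">rep{tr.replicate_id}|t{rec.generation}|n{c}\n{seq}\n")


def load_trajectory_fasta(path, config: SimulationConfig | None = None) -> list[Trajectory]:
    rows: dict[int, dict[int, list]] = {}
    L = None
    header = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(";"):
                continue
            if line.startswith(">"):
                header = line[1:]
                continue
            rep_s, t_s, n_s = header.split("|")
            rep, gen, count = int(rep_s[3:]), int(t_s[1:]), int(n_s[1:])
            g = np.array([1 if ch == "T" else -1 for ch in line], dtype=np.int8)
            L = len(g)
            rows.setdefault(rep, {}).setdefault(gen, []).append((g, count))
    return _assemble(rows, L, config)


def _assemble(rows, L, config) -> list[Trajectory]:
    trajs = []
    for rep in sorted(rows):
        records = []
        for gen in sorted(rows[rep]):
            gs, cs = zip(*rows[rep][gen])
            records.append(TrajectoryRecord(gen, np.array(gs, dtype=np.int8),
                                            np.array(cs, dtype=np.int64)))
        n = records[0].n_samples
        cfg = config or SimulationConfig(N=max(n, 2), L=L,
                                         T=records[-1].generation)
        trajs.append(Trajectory(rep, cfg, "file", tuple(records)))
    return trajs
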