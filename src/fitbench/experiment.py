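"""End-to-end benchmark scenarios: simulate, infer with both methods, score.

The standard conditions evolve N=1000 haploids with L=25 loci for T=30
generations at outcrossing rate r=0.5.  Two landscape families are studied:

* additive-only (sigma_fij = 0), single replicate, crossing mutation rate
  mu in {0.003, 0.01} with additive dispersion sigma_fi in {0.01, 0.05};
* additive + pairwise epistasis (sigma_fij = 0.002, mu = 0.01), 30
  replicates, sweeping sigma_fi in {0.005, 0.05, 0.1} to move from
  epistasis-dominated to additive-dominated fitness variation.

Seeding is hierarchical: one experiment seed derives the landscape stream
and per-replicate simulator streams through disjoint SeedSequence spawn
keys, so increasing the replicate count changes neither the landscape nor
the earlier replicates — replicate-count curves compare nested data sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .evaluate import EvaluationReport, evaluate_run
from .landscape import FitnessLandscape, sample_landscape
from .mpl import DEFAULT_GAMMA, infer_mpl
from .tqle import DEFAULT_VARIANT, infer_tqle
from .freqstats import DEFAULT_LAMBDA
from .wfsim import SimulationConfig, Trajectory, simulate_replicates

log = logging.getLogger("fitbench")


@dataclass(frozen=True)
class Scenario:
    """One benchmark condition: landscape family + simulation + inference knobs."""

    name: str
    sigma_fi: float
    sigma_fij: float
    mu: float = 0.01
    N: int = 1000
    L: int = 25
    T: int = 30
    r: float = 0.5
    n_replicates: int = 1
    replicate_counts: tuple[int, ...] = ()
    seed: int = 0
    gamma: float = DEFAULT_GAMMA
    lam: float = DEFAULT_LAMBDA
    tqle_variant: str | None = None  # None -> additive_only iff sigma_fij == 0

    def config(self) -> SimulationConfig:
        return SimulationConfig(N=self.N, L=self.L, T=self.T, r=self.r,
                                mu=self.mu, n_replicates=self.n_replicates,
                                seed=self.seed)

    def variant(self) -> str:
        if self.tqle_variant is not None:
            return self.tqle_variant
        return "additive_only" if self.sigma_fij == 0 else DEFAULT_VARIANT

    def counts(self) -> tuple[int, ...]:
        return self.replicate_counts or (self.n_replicates,)

    def with_seed(self, seed: int) -> "Scenario":
        return replace(self, seed=seed)


# Benchmark presets.  Additive-only rows use a single replicate; epistatic
# rows aggregate 30 independent realizations.
PRESETS: dict[str, Scenario] = {
    "additive-weak":   Scenario("additive-weak", sigma_fi=0.01, sigma_fij=0.0, mu=0.003),
    "additive-mid":    Scenario("additive-mid", sigma_fi=0.01, sigma_fij=0.0, mu=0.01),
    "additive-strong": Scenario("additive-strong", sigma_fi=0.05, sigma_fij=0.0, mu=0.01),
    "epistatic-low":   Scenario("epistatic-low", sigma_fi=0.005, sigma_fij=0.002,
                                mu=0.01, n_replicates=30),
    "epistatic-mid":   Scenario("epistatic-mid", sigma_fi=0.05, sigma_fij=0.002,
                                mu=0.01, n_replicates=30),
    "epistatic-high":  Scenario("epistatic-high", sigma_fi=0.1, sigma_fij=0.002,
                                mu=0.01, n_replicates=30),
}


def get_preset(name: str, seed: int = 0, **overrides) -> Scenario:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return replace(PRESETS[name], seed=seed, **overrides)


@dataclass
class ScenarioResult:
    scenario: Scenario
    landscape: FitnessLandscape
    trajectories: list[Trajectory]
    # (method, n_replicates) -> EvaluationReport
    reports: dict[tuple[str, int], EvaluationReport] = field(default_factory=dict)


def landscape_for(sc: Scenario) -> FitnessLandscape:
    """Ground-truth landscape for a scenario (seed-derived, replicate-independent)."""
    ss = np.random.SeedSequence(entropy=sc.seed, spawn_key=(1,))
    return sample_landscape(sc.L, sc.sigma_fi, sc.sigma_fij, ss)


def run_scenario(sc: Scenario) -> ScenarioResult:
    """Simulate, infer with tQLE and MPL at each replicate count, evaluate."""
    fl = landscape_for(sc)
    cfg = sc.config()
    log.info("scenario %s: seed=%d sigma_fi=%g sigma_fij=%g mu=%g",
             sc.name, sc.seed, sc.sigma_fi, sc.sigma_fij, sc.mu)
    trajs = simulate_replicates(fl, cfg)
    result = ScenarioResult(sc, fl, trajs)
    for n in sc.counts():
        if n > len(trajs):
            raise ValueError(f"replicate count {n} exceeds simulated {len(trajs)}")
        subset = trajs[:n]
        est_tqle = infer_tqle(subset, variant=sc.variant(), lam=sc.lam).as_inferred(
            {"scenario": sc.name, "seed": sc.seed})
        est_mpl = infer_mpl(subset, mu=sc.mu, gamma=sc.gamma, lam=sc.lam)
        for est, rep in zip((est_tqle, est_mpl),
                            evaluate_run(subset, fl, [est_tqle, est_mpl])):
            result.reports[(est.method, n)] = rep
            log.info("  %s n=%d: spearman_all=%.3f top5=%.3f",
                     est.method, n, rep.spearman_all, rep.spearman_top5)
    return result


def compare_methods(results: ScenarioResult | list[ScenarioResult]) -> pd.DataFrame:
    """Long-format comparison table across scenarios, methods, replicate counts."""
    if isinstance(results, ScenarioResult):
        results = [results]
    if not results:
        raise ValueError("no results supplied")
    rows = []
    for res in results:
        for (method, n), rep in sorted(res.reports.items()):
            metrics = {
                "spearman_all": rep.spearman_all,
                "spearman_top5": rep.spearman_top5,
                "fi_pearson": rep.param_recovery["fi"].pearson,
                "fi_slope": rep.param_recovery["fi"].slope,
                "fi_rmse": rep.param_recovery["fi"].rmse,
            }
            if rep.param_recovery["fij"] is not None:
                metrics["fij_spearman"] = rep.param_recovery["fij"].spearman
            for metric, value in metrics.items():
                rows.append({"scenario": res.scenario.name, "seed": res.scenario.seed,
                             "method": method, "n_replicates": n,
                             "metric": metric, "value": value})
    return pd.DataFrame(rows)


def sweep(preset_names: list[str] | None = None, seed: int = 0,
          replicate_counts: tuple[int, ...] | None = None) -> list[ScenarioResult]:
    """Run a batch of presets under one experiment seed."""
    names = preset_names or list(PRESETS)
    out = []
    for name in names:
        sc = get_preset(name, seed=seed)
        if replicate_counts is not None:
            valid = tuple(n for n in replicate_counts if n <= sc.n_replicates)
            sc = replace(sc, replicate_counts=valid or (sc.n_replicates,))
        out.append(run_scenario(sc))
    return out
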