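"""Scoring of inferred fitness landscapes against ground truth.

The central evaluation philosophy is order, not magnitude: what matters for
prediction is how genotypes rank by fitness, so the headline metrics are
Spearman rank correlations over all observed genotypes and, separately,
within the elite top 5% of true fitness.  Parameter-level recovery (Pearson,
Spearman, regression slope, RMSE for f_i and f_ij) and descriptive
distribution analyses (additive/epistatic decomposition, Gumbel fits,
initial-vs-final Kolmogorov-Smirnov distances) complete the report.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as sps

from .landscape import FitnessLandscape, InferredLandscape, fitness_of_many
from .wfsim import Trajectory

TOP_FRACTION = 0.05


@dataclass(frozen=True)
class ParamRecovery:
    pearson: float
    spearman: float
    slope: float
    rmse: float


@dataclass(frozen=True)
class GumbelFit:
    location: float
    scale: float
    orientation: str
    loglik: float
    converged: bool


@dataclass
class EvaluationReport:
    method: str
    spearman_all: float
    spearman_top5: float
    rank_pairs: list            # (true_rank, inferred_rank) for the elite set
    param_recovery: dict        # {"fi": ParamRecovery, "fij": ParamRecovery|None}
    decomposition: dict         # moments of (total, additive, epistatic) at 0 and T
    gumbel_fit: GumbelFit | None
    ks_initial_vs_final: dict   # per-component KS distances
    n_genotypes: int
    hyperparams: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        doc = asdict(self)
        text = json.dumps(_plain(doc), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def predict_fitness(genotypes: np.ndarray, est: InferredLandscape) -> np.ndarray:
    """Predicted fitness of each genotype under an inferred landscape.

    Additive-only when ``fij_star`` is absent; otherwise the full quadratic
    form with f0 = 0.
    """
    total, additive, _ = fitness_of_many(genotypes, est.as_landscape())
    return total if est.fij_star is not None else additive


def spearman_ranks(true_vals: np.ndarray, pred_vals: np.ndarray,
                   subset: str = "all",
                   top_fraction: float = TOP_FRACTION) -> float:
    """Midrank Spearman correlation, optionally within the true-fitness elite.

    ``subset="top"`` selects the ceil(top_fraction * n) genotypes of highest
    TRUE fitness and correlates, within that subset, the true ranks against
    inferred ranks computed on the FULL set (the elite's predicted positions
    in the global ordering).
    """
    t = np.asarray(true_vals, dtype=float)
    p = np.asarray(pred_vals, dtype=float)
    if t.size != p.size or t.size < 2:
        raise ValueError("need equal-length inputs with at least 2 entries")
    if subset == "all":
        rho = sps.spearmanr(t, p).statistic
        return float(rho)
    if subset != "top":
        raise ValueError("subset must be 'all' or 'top'")
    k = math.ceil(top_fraction * t.size)
    if k < 2:
        raise ValueError("elite subset has fewer than 2 genotypes")
    # ranks over the full universe (rank 1 = highest fitness), midranks for ties
    true_rank = sps.rankdata(-t, method="average")
    pred_rank = sps.rankdata(-p, method="average")
    elite = np.argsort(-t, kind="stable")[:k]
    rho = sps.spearmanr(true_rank[elite], pred_rank[elite]).statistic
    return float(rho)


def elite_rank_pairs(true_vals: np.ndarray, pred_vals: np.ndarray,
                     top_fraction: float = TOP_FRACTION) -> list[tuple[float, float]]:
    """(true_rank, inferred_rank) for the top-fraction elite by true fitness."""
    t = np.asarray(true_vals, dtype=float)
    p = np.asarray(pred_vals, dtype=float)
    k = math.ceil(top_fraction * t.size)
    true_rank = sps.rankdata(-t, method="average")
    pred_rank = sps.rankdata(-p, method="average")
    elite = np.argsort(-t, kind="stable")[:k]
    return [(float(true_rank[i]), float(pred_rank[i])) for i in elite]


def rank_universe(trajs: list[Trajectory],
                  fl: FitnessLandscape) -> tuple[np.ndarray, np.ndarray]:
    """Unique genotypes observed anywhere in the trajectories, ranked by truth.

    Returns ``(genotypes, true_fitness)`` sorted by decreasing true fitness;
    ties broken by first-observation order (deterministic).
    """
    if not trajs:
        raise ValueError("no trajectories supplied")
    blocks = [rec.genotypes for tr in trajs for rec in tr.records]
    X = np.vstack(blocks)
    # first-observation order: unique returns lexicographic; recover first index
    _, first_idx = np.unique(X, axis=0, return_index=True)
    uniq = X[np.sort(first_idx)]
    total, _, _ = fitness_of_many(uniq, fl)
    order = np.argsort(-total, kind="stable")
    return uniq[order], total[order]


def decompose_distributions(trajs: list[Trajectory] | Trajectory,
                            fl: FitnessLandscape, at: str = "final") -> dict:
    """Count-weighted fitness-component samples of the population.

    Returns per-individual arrays (pooled over replicates) of total, additive
    and epistatic fitness at the initial or final recorded generation, plus
    their means/variances and histograms.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    if at not in ("initial", "final"):
        raise ValueError("at must be 'initial' or 'final'")
    tot, add, epi = [], [], []
    for tr in trajs:
        rec = tr.records[0] if at == "initial" else tr.records[-1]
        t, a, e = fitness_of_many(rec.genotypes, fl)
        tot.append(np.repeat(t, rec.counts))
        add.append(np.repeat(a, rec.counts))
        epi.append(np.repeat(e, rec.counts))
    out = {}
    for name, vals in (("total", np.concatenate(tot)),
                       ("additive", np.concatenate(add)),
                       ("epistatic", np.concatenate(epi))):
        hist, edges = np.histogram(vals, bins=40)
        out[name] = {"samples": vals, "mean": float(vals.mean()),
                     "var": float(vals.var()),
                     "hist": hist, "bin_edges": edges}
    return out


def fit_gumbel(samples: np.ndarray, orientation: str = "min") -> GumbelFit:
    """Maximum-likelihood two-parameter Gumbel fit (min- or max-oriented).

    Descriptive only: used to characterize the non-Gaussian shape of final
    additive-fitness distributions, never to gate inference quality.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 20:
        raise ValueError("need at least 20 samples")
    if orientation not in ("min", "max"):
        raise ValueError("orientation must be 'min' or 'max'")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate (constant) sample: zero scale")
    dist = sps.gumbel_l if orientation == "min" else sps.gumbel_r
    loc, scale = dist.fit(x)
    ll = float(dist.logpdf(x, loc, scale).sum())
    converged = bool(np.isfinite(ll) and scale > 0)
    return GumbelFit(float(loc), float(scale), orientation, ll, converged)


def _param_recovery(true_v: np.ndarray, est_v: np.ndarray) -> ParamRecovery:
    t = np.asarray(true_v, dtype=float).ravel()
    e = np.asarray(est_v, dtype=float).ravel()
    if np.ptp(t) == 0 or np.ptp(e) == 0:
        pearson = spearman = slope = float("nan")
    else:
        pearson = float(sps.pearsonr(t, e).statistic)
        spearman = float(sps.spearmanr(t, e).statistic)
        slope = float(np.polyfit(t, e, 1)[0])
    rmse = float(np.sqrt(np.mean((t - e) ** 2)))
    return ParamRecovery(pearson, spearman, slope, rmse)


def ks_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov distance."""
    return float(sps.ks_2samp(a, b).statistic)


def evaluate_run(trajs: list[Trajectory], truth: FitnessLandscape,
                 estimates: list[InferredLandscape],
                 top_fraction: float = TOP_FRACTION) -> list[EvaluationReport]:
    """Full evaluation of one or more inferred landscapes against truth."""
    universe, true_fit = rank_universe(trajs, truth)
    init = decompose_distributions(trajs, truth, at="initial")
    fin = decompose_distributions(trajs, truth, at="final")
    ks = {name: ks_distance(init[name]["samples"], fin[name]["samples"])
          for name in ("total", "additive", "epistatic")}
    try:
        gumbel = fit_gumbel(fin["additive"]["samples"], orientation="min")
    except ValueError:
        gumbel = None
    decomposition = {
        at: {name: {k: v for k, v in comp.items() if k != "samples"}
             for name, comp in d.items()}
        for at, d in (("initial", init), ("final", fin))
    }
    reports = []
    for est in estimates:
        pred = predict_fitness(universe, est)
        rec = {"fi": _param_recovery(truth.fi, est.fi_star), "fij": None}
        if est.fij_star is not None:
            iu = np.triu_indices(truth.L, k=1)
            rec["fij"] = _param_recovery(truth.fij[iu], est.fij_star[iu])
        reports.append(EvaluationReport(
            method=est.method,
            spearman_all=spearman_ranks(true_fit, pred, "all"),
            spearman_top5=spearman_ranks(true_fit, pred, "top", top_fraction),
            rank_pairs=elite_rank_pairs(true_fit, pred, top_fraction),
            param_recovery=rec,
            decomposition=decomposition,
            gumbel_fit=gumbel,
            ks_initial_vs_final=ks,
            n_genotypes=int(universe.shape[0]),
            hyperparams=dict(est.hyperparams),
        ))
    return reports


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
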