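"""Infer pairwise epistasis and genotype fitness ranks with pooled replicates.

In the epistasis-dominated regime (sigma_fi = 0.005, sigma_fij = 0.002) the
epistatic terms carry most of the fitness variance; recovering them requires
pooling many replicate trajectories.  tQLE infers both additive and pairwise
parameters; MPL is additive-only, so epistasis acts as a confounder for it.
"""

import numpy as np
from scipy.stats import spearmanr

import fitbench as fb
from fitbench.experiment import landscape_for

sc = fb.get_preset("epistatic-low", seed=1)
fl = landscape_for(sc)
trajs = fb.simulate_replicates(fl, sc.config())

est_tqle = fb.infer_tqle(trajs, variant="rc_4mu").as_inferred()
est_mpl = fb.infer_mpl(trajs)

iu = np.triu_indices(fl.L, k=1)
rho_fij = spearmanr(fl.fij[iu], est_tqle.fij_star[iu]).statistic
print(f"tQLE Spearman(fij*, fij) over {iu[0].size} pairs: {rho_fij:.3f}")

rep_tqle, rep_mpl = fb.evaluate_run(trajs, fl, [est_tqle, est_mpl])
for rep in (rep_tqle, rep_mpl):
    print(f"{rep.method}: all-sequence Spearman = {rep.spearman_all:.3f}, "
          f"top-5% Spearman = {rep.spearman_top5:.3f} "
          f"({rep.n_genotypes} unique genotypes ranked)")

# Expected: fij recovery around 0.7; tQLE orders genotypes better than MPL
# here because MPL cannot see the dominant epistatic component.
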