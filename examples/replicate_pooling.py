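"""How inference quality depends on the number of pooled replicates.

tQLE pools replicate moments and benefits strongly from more replicates in
the epistasis-dominated regime; MPL sums per-replicate sufficient statistics
and is comparatively insensitive to the replicate count.
"""

import fitbench as fb

sc = fb.get_preset("epistatic-mid", seed=1, replicate_counts=(1, 5, 30))
res = fb.run_scenario(sc)

print(f"scenario {sc.name}: sigma_fi={sc.sigma_fi}, sigma_fij={sc.sigma_fij}")
print(f"{'method':>6} {'replicates':>10} {'Spearman(all)':>14} {'Spearman(top5%)':>16}")
for (method, n), rep in sorted(res.reports.items()):
    print(f"{method:>6} {n:>10} {rep.spearman_all:>14.3f} {rep.spearman_top5:>16.3f}")

# MPL's all-sequence column barely moves with replicate count, while tQLE
# climbs as pooled moments sharpen its coupling estimates.
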