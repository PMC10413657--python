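"""Co-assembly enrichment between inheritance groups, with a bootstrap.

Autosomal-dominant (AD) disease genes — candidates for dominant-negative
effects — undergo cotranslational assembly less often than autosomal-
recessive (AR) genes.  We generate a gene table at co-assembly rates of
24.0% (AD) and 35.6% (AR), compare the groups, and bootstrap a stratum of
interface shifts.
"""

import numpy as np

from assembly_buffer import (
    bootstrap_shift,
    gen_gene_table,
    group_compare,
    jeffreys_interval,
)

table = gen_gene_table(
    {"AD": 20000, "AR": 20000}, {"AD": 0.240, "AR": 0.356}, seed=2
)
res = group_compare(
    table.records,
    lambda r: r.inheritance == "AD",
    lambda r: r.inheritance == "AR",
)
print(
    f"AD: {res.k1}/{res.n1} co-assembling ({100 * res.p1:.1f}%), "
    f"AR: {res.k2}/{res.n2} ({100 * res.p2:.1f}%)"
)
print(
    f"odds ratio {res.odds_ratio:.2f} "
    f"[95% CI {res.ci_low:.2f}-{res.ci_high:.2f}], P = {res.p_value:.2e}"
)
lo, hi = jeffreys_interval(res.k1, res.n1)
print(f"68% Jeffreys interval for the AD proportion: [{lo:.3f}, {hi:.3f}]")

rng = np.random.default_rng(0)
obs = [("DN", x) for x in rng.normal(0.55, 0.10, size=50)]
boot = bootstrap_shift(obs, basemean=0.49, B=10000, seed=1)["DN"]
print(
    f"\nDN interface shift: {boot.point_shift:+.1f}% "
    f"[95% CI {boot.ci_low:+.1f}%, {boot.ci_high:+.1f}%], "
    f"bootstrap P = {boot.p_boot:.4f} ({boot.B} resamples)"
)
print(
    "\nAn odds ratio near 0.57 means the odds of co-assembly for an AD gene "
    "are roughly half those of an AR gene; the positive bootstrap shift "
    "marks C-terminally displaced interfaces."
)
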