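"""Validation statistics: gene-set enrichment and transcription-inhibition deltas.

Two in-silico checks used to validate called LR pairs: (1) enrichment of an
annotation set (e.g. essential genes) among the called genes, with
hypergeometric tails; (2) the effect of blocking zygotic genome activation,
measured per pair as |log10(IS_inhibited + 1) - log10(IS_late2cell + 1)|,
with affected pairs found by two rounds of hierarchical clustering.
"""

import numpy as np
import pandas as pd

from lrcausal import compare_delta_groups, delta_analysis, enrichment_ratio, find_affected_pairs
from lrcausal.datatypes import GeneSet

rng = np.random.default_rng(0)
universe = GeneSet("all_genes", [f"g{i}" for i in range(1000)])
essential = GeneSet("essential", [f"g{i}" for i in range(200)])          # 20% of genome
called = GeneSet("called_lr_genes", [f"g{i}" for i in range(0, 300, 5)])  # enriched draw
res = enrichment_ratio(essential, called, universe)
print(f"enrichment of {res.set_a} in {res.set_b}: ratio={res.ratio:.2f} "
      f"(overlap {res.overlap}/{len(called.members)}), p_upper={res.p_upper:.2e}")
print("-> the called genes carry twice the background essential-gene fraction\n")

n = 40
base = rng.uniform(5, 10, n)
inhibited = np.where(np.arange(n) < 8, base / 10, base)  # 8 pairs collapse when inhibited
table = pd.DataFrame(
    {
        "early_2cell": base + rng.normal(0, 0.05, n),
        "late_2cell": base + rng.normal(0, 0.05, n),
        "inhibited": inhibited + rng.normal(0, 0.05, n),
    },
    index=[f"L{i}-R{i}" for i in range(n)],
)
deltas = {str(r.pair): r.delta for r in delta_analysis(table)}
affected = find_affected_pairs(table)
print(f"pairs affected by transcription inhibition: {sorted(affected)}")

elr_like = [deltas[p] for p in deltas if p not in affected]
non_elr = [deltas[p] for p in affected]
t, p = compare_delta_groups(np.array(elr_like), np.array(non_elr))
print(f"one-sided Welch t-test (unaffected pairs lower delta): t={t:.1f}, p={p:.2e}")
print("-> pairs outside the affected cluster show significantly smaller "
      "inhibition deltas, i.e. their signaling is less ZGA-dependent")
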