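"""Deriving the co-variation cutoff by the double-tangent construction.

Ranking the positive screen correlations ascending gives a concave curve;
chord AB (first to last point) locates tangency point C at maximal
perpendicular distance, chord AC locates D, and D's ordinate is the cutoff
below which the curve is roughly linear (background correlation).
"""

import numpy as np

from lrcausal import derive_cutoff, screen_covarying
from lrcausal.ordering import order_cells
from lrcausal.synthetic import SimulationConfig, simulate_embryo

cfg = SimulationConfig(seed=0, n_lr_pairs=200, planted=["feedback"] * 20)
mat, meta, lr_db, _, _ = simulate_embryo(cfg)
ordering = order_cells(meta)
results = screen_covarying(mat, ordering, lr_db, cutoff=0.0)
pccs = np.array([r.pcc for r in results])
print(f"screened {len(pccs)} pairs: {sum(pccs > 0)} positive, {sum(pccs < 0)} negative")

pos = derive_cutoff(pccs, side="positive")
neg = derive_cutoff(pccs, side="negative")
print(f"derived cutoffs: positive {pos:.4f}, negative {neg:.4f}")
final = round(max(abs(pos), abs(neg)), 2)
print(f"final |PCC| cutoff (max of the two, rounded to 2 dp): {final}")
print("(pairs above the positive / below the negative cutoff are the "
      "co-varying candidates passed to the Granger stage)")
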