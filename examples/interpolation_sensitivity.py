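"""How the interpolation bandwidth distorts Granger conclusions.

Interpolating two series onto a common grid smooths them; the smoother the
series, the fewer effective degrees of freedom the Granger F test sees and
the more it rejects.  This sweep quantifies the false-positive ratio on
independent AR(1) pairs and the detection rate on a truly coupled pair,
per bandwidth.
"""

import pandas as pd

from lrcausal import interpolation_sensitivity

winsz_grid = [0.02, 0.05, 0.1, 0.3]
fp = interpolation_sensitivity("independent", winsz_grid, reps=200, rng=0)
power = interpolation_sensitivity("coupled", winsz_grid, reps=100, rng=0)
table = pd.DataFrame(
    {
        "winsz": winsz_grid,
        "false_positive_ratio": fp["rejection_rate"].to_numpy(),
        "true_detection_rate": power["rejection_rate"].to_numpy(),
    }
)
print(table.to_string(index=False))
print(
    "\n-> false positives grow with the bandwidth: at the default winsz=0.1 the\n"
    "   test on interpolated independent series rejects far above the nominal\n"
    "   1% level, which is why interpolated-grid Granger p-values must be read\n"
    "   as a screen, not as calibrated significance (see docs/methods.md)."
)
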