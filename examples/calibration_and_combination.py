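"""Calibrating raw correlations and combining evidence channels.

Builds a labeled pair set where pairs with r > 0.5 are 90% true associations
and the rest 10%, fits the sliding-window + isotonic calibration curve, and
shows the prior-corrected noisy-OR combination of two channel scores.
"""

import numpy as np
import pandas as pd

from assocnet import calibrate, combine_scores
from assocnet.scoring import LabeledPairs

rng = np.random.default_rng(0)
n = 10_000
r = rng.uniform(-1, 1, n)
labels = (rng.random(n) < np.where(r > 0.5, 0.9, 0.1)).astype(int)
pairs = LabeledPairs(
    table=pd.DataFrame(
        {
            "gene_a": [f"x{i}" for i in range(n)],
            "gene_b": [f"y{i}" for i in range(n)],
            "r": r,
            "label": labels,
        }
    )
)

curve = calibrate(pairs, window_size=500)
print(f"prior (global positive fraction): {curve.prior:.3f}")
for raw in (-0.5, 0.0, 0.4, 0.6, 0.8):
    print(f"  posterior at r={raw:+.1f}: {float(curve(raw)):.3f}")
print("The curve recovers the planted precisions: ~0.1 below r=0.5, ~0.9 above.")

print()
s = combine_scores({"coexpression_single": 0.6, "coexpression_dual": 0.4}, prior=0.1)
print(f"combine(0.6, 0.4 | prior 0.1) = {s:.4f}")
print("Two independent channels agreeing push the combined confidence above")
print("either single channel (noisy-OR in prior-corrected space).")
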