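"""Inspect what the forests learned: importance rankings and the position profile.

Trains RF-TETRA and RF-HOT on the canonical 1 Mbp benchmark and shows
that the top-ranked 4-mers and the most important one-hot positions
recover the planted Pribnow-box (TATAAT at TSS-relative -12..-7).
"""

import numpy as np

import promforest as pf
from promforest.model import GRID_FAST

bench = pf.default_benchmark()

tetra, _ = pf.train_rf(
    pf.encode_set(bench.train_set, "TETRA"), grid=GRID_FAST, folds=3, seed=0
)
print("top-5 4-mers by impurity importance (mean +/- sd across trees):")
for i, e in enumerate(pf.impurity_importance(tetra).top(5), 1):
    print(f"  {i}. {e.feature}  {e.mean:.4f} +/- {e.sd:.4f}")

hot, _ = pf.train_rf(
    pf.encode_set(bench.train_set, "HOT"), grid=GRID_FAST, folds=3, seed=0
)
profile = pf.position_profile(pf.impurity_importance(hot))
per_pos = profile.per_position()
top = np.argsort(-per_pos)[:6]
print("most important TSS-relative positions (one-hot model):")
for i in sorted(top):
    print(f"  position {profile.position_labels[i]:+d}: {per_pos[i]:.4f}")
print(
    "The highest-importance positions cluster ~10 bp upstream of the TSS\n"
    "with A/T channels dominating — the forests rediscover the TATAAT\n"
    "(Pribnow-Schaller) box rather than memorising arbitrary sequence."
)
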