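"""Derive HU windows from a node-pixel pool and apply them.

Builds a synthetic pool of lymph-node Hounsfield units, trims its tails
at four symmetric quantile pairs to obtain detection windows, and shows
how a windowed pixel maps onto [0, 1].
"""

import numpy as np

from pelvidet import QuantileRange, WINDOW_PRESETS, apply_window, derive_quantile_window

rng = np.random.default_rng(0)
pool = np.round(rng.normal(45, 35, 50_000))  # node-pixel HU samples

print("window derived from each quantile pair (low HU, high HU):")
for lo, hi in [(0.5, 99.5), (1, 99), (1.5, 98.5), (2, 98)]:
    w = derive_quantile_window(pool, QuantileRange(lo, hi))
    print(f"  ({lo:>4}%, {hi:>5}%)  ->  ({w.low_hu:+6.0f}, {w.high_hu:+6.0f})")
print("narrower quantile pairs exclude more of the HU tails, giving tighter windows.")

soft = WINDOW_PRESETS["soft_tissue"]
px = np.array([-200.0, -125.0, 50.0, 225.0, 400.0])
print(f"\npixels {px.tolist()} under the soft-tissue window "
      f"({soft.low_hu:.0f}, {soft.high_hu:.0f}):")
print(" ", np.round(apply_window(px, soft), 3).tolist())
print("values outside the window clip to 0 or 1; the window midpoint maps to 0.5.")
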