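"""Stable-point count versus biodiversity K: rise then saturation.

The mean number of homeostatic states of a random community increases
with the number of biotic components and then saturates at the large-K
(Gaussian-field) value; wider niches saturate lower.
"""

import numpy as np

from reinworld import (ModelConfig, expected_stable_points, saturation_sweep,
                       threshold_K)

K_grid = [1, 2, 5, 10, 20, 50, 100, 200, 500, 1000]
rng = np.random.default_rng(0)
for width in (5.0, 10.0):
    cfg = ModelConfig(K=100, n_env=1, niche_width=width, seed=0)
    df = saturation_sweep(K_grid, cfg, n_populations=200, rng=rng)
    print(f"niche width sigma = {width:.0f} "
          f"(large-K limit {expected_stable_points(1, 100.0, width):.2f}, "
          f"threshold K ~ {threshold_K(100.0, width):.0f}):")
    print("  K:     " + "  ".join(f"{k:5d}" for k in df["K"]))
    print("  count: " + "  ".join(f"{m:5.2f}" for m in df["mean"]))
print("interpretation: more diversity does not destabilise the system —")
print("the number of homeostatic states saturates once K exceeds a few")
print("components per niche width across the essential range.")
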