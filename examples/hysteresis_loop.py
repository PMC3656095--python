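"""Hysteresis of the occupied homeostatic state under slow forcing.

A force with three zero crossings (two stable states separated by an
unstable one) is swept quasi-statically up and back down in the external
forcing P; the occupied state jumps at different forcings on the two
branches, opening a loop.
"""

import numpy as np

from reinworld import ModelConfig, find_stable_points_1d, hysteresis_sweep

cfg = ModelConfig(K=1, n_env=1, dt=0.05)
a, c = 0.08, 300.0
force = lambda x: -((x - 50.0) ** 3) / c + a * (x - 50.0)

pts = find_stable_points_1d(force, 100.0, h=0.5)
print("crossings:", [(p.classification, round(float(p.location[0]), 1))
                     for p in pts])
loop = hysteresis_sweep(force, cfg, p_lo=-1.0, p_hi=1.0, n_steps=101)
p_up = loop.up_transitions[0][0]
p_down = loop.down_transitions[0][0]
ef = np.sqrt(a * c / 3.0)
print(f"up-sweep jump at P = {p_up:+.3f} (analytic fold {force(50+ef):+.3f})")
print(f"down-sweep jump at P = {p_down:+.3f} (analytic fold {-force(50+ef):+.3f})")
print(f"open loop width: {p_up - p_down:.3f} in forcing units")
print("interpretation: once the system has jumped to the upper state,")
print("recovering the lower one requires lowering P past the other fold —")
print("the regulated state depends on forcing history, not just on P.")
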