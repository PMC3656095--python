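"""Large-K crossing statistics: closed form, Rice oracle, Monte-Carlo.

In the large-K limit the summed biotic force per axis is a stationary
Gaussian process; its expected number of down-crossings over the
essential range — the expected number of homeostatic states — is
R / (2 sqrt(2) pi sigma), and depends only on the ratio R/sigma and not
on the niche shape family.
"""

import numpy as np

from reinworld import (NicheShape, build_kernel, expected_stable_points,
                       mc_gp_stable_count, rice_downcrossings)

rng = np.random.default_rng(0)
print("(R, sigma)   closed form   Rice oracle   Monte-Carlo (200 fields)")
for R, s in ((100.0, 5.0), (100.0, 10.0), (200.0, 10.0)):
    kern = build_kernel(NicheShape("gaussian", s))
    mc, se = mc_gp_stable_count(kern, R, n_fields=200, rng=rng)
    print(f"({R:5.0f},{s:3.0f})   {expected_stable_points(1, R, s):11.3f}"
          f"   {rice_downcrossings(kern, R, numeric=True):11.3f}"
          f"   {mc:.3f} +/- {se:.3f}")
print()
print("niche-shape invariance at matched characteristic width 5:")
for fam in ("gaussian", "skewed", "bimodal"):
    kern = build_kernel(NicheShape(fam, 5.0))
    mc, se = mc_gp_stable_count(kern, 100.0, n_fields=200, rng=rng)
    print(f"  {fam:9s}: {mc:.3f} +/- {se:.3f}")
print("interpretation: (100,5) and (200,10) coincide (only R/sigma matters)")
print("and the three families agree — the shape of the niche function is")
print("irrelevant once its characteristic width is fixed.")
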