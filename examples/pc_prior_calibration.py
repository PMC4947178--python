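"""Build and calibrate the penalized-complexity prior on the variance.

The prior places an exponential distribution on the complexity distance
d(v) = sqrt(2 KL(v)) from the no-variability base model v = 0, then picks
the exponential rate lambda so that only tail_alpha = 1% of prior mass lies
above the conservative threshold v_L = 0.142.  Shown for two bulk means:
an even 0.5 and 0.23 (a typical moderately edited site).
"""

import numpy as np

from editvar import PCPrior

for p in (0.5, 0.23):
    v_max = p * (1 - p)
    prior = PCPrior(p=p, n_ref=20, v_l=min(0.142, 0.9 * v_max), tail_alpha=0.01).calibrate()
    print(f"\nbulk mean p = {p}: variance support [0, {v_max:.4f}]")
    print(f"  d(v_L)={prior.distance(prior.v_l):.4f}  d_max={prior.d_max:.4f}  "
          f"lambda={prior.lam:.4f}")
    print(f"  integrated mass above v_L={prior.v_l}: {prior.tail_mass():.5f}")
    for v in (0.001, 0.01, 0.05, prior.v_l):
        print(f"  prior density at v={v:<6}: {prior.density(v):10.4f}")

print(
    "\nThe density is largest near v=0 and decays with complexity distance:"
    "\nwithout evidence in the data, inference shrinks towards equal"
    "\nediting rates across cells, and only 1% of prior mass exceeds v_L."
)
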