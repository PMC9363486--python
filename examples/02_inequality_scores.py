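"""Gini and Palma statistics on coupling-contribution profiles.

Constructs a flat (normal-like) and a polarized (anomalous-like) profile of
total primary-capsule contributions M_j and prints both inequality scores:
polarized routing concentrates the mass, which both statistics pick up.
"""

import numpy as np

from capsanomaly import gini, palma

rng = np.random.default_rng(1)

flat = rng.uniform(0.9, 1.1, size=64)          # every capsule contributes alike
polarized = rng.uniform(0.02, 0.05, size=64)   # a single dominant route
polarized[7] = 4.0

for name, m in (("flat", flat), ("polarized", polarized)):
    print(f"{name:>10s}: gini = {gini(m):.4f}   palma = {palma(m):.4f}")

# Gini ranges over [0, (n-1)/n]: 0 for perfect equality, toward 1 when one
# entry holds all the mass. Palma is the 90th/40th percentile ratio, 1.0 for
# a constant profile. Both are scale-invariant:
print("scale-invariant:", np.isclose(gini(7.3 * flat), gini(flat)))
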