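"""Dynamic routing by agreement on a tiny hand-sized instance.

Builds three primary capsules and two class capsules, routes for three
iterations, and prints the class-capsule norms and the coupling table.
Couplings start uniform (0.5 each) and drift toward the class capsule each
primary capsule agrees with.
"""

import numpy as np

from capsanomaly import route, squash

rng = np.random.default_rng(0)

u = squash(rng.normal(size=(3, 4)))       # 3 primary capsules, 4-dim output
W = rng.normal(size=(3, 2, 4, 4))         # transforms to 2 class capsules

out = route(u, W, iterations=3, record_couplings=True)

print("class-capsule norms:", np.round(out["norms"], 4))
print("coupling table c_ij (rows = primary capsules):")
print(np.round(out["c"], 4))
for it, c in enumerate(out["history"]):
    print(f"  iteration {it}: per-capsule spread {np.round(c[:, 0] - 0.5, 4)}")

# The norms are presence probabilities (always < 1, squash bound); each row
# of c sums to 1 — a primary capsule divides its vote between the classes.
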