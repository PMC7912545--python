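"""Simulate two purebred studbooks and a staged composite breed.

Builds two closed base populations (A and B), runs the default five-stage
crossing scheme, and prints the census and blood-class composition of the
composite.  The blood fraction of each composite animal is the proportion of
its genome expected to derive from breed A.
"""

from collections import Counter

import pedstruct as ps

cfg_a = ps.SimulationConfig(n_founders_per_breed=30, n_generations=4, seed=1)
cfg_b = ps.SimulationConfig(n_founders_per_breed=30, n_generations=4, seed=2)
ped, fractions = ps.simulate_composite(cfg_a, cfg_b, seed=3)

print(f"total animals: {len(ped)}")
for breed in ("A", "B", "AB"):
    n = sum(1 for b in ped.breed if str(b) == breed)
    print(f"  breed {breed}: {n}")

blood = Counter(
    round(fractions[ped.ids[i]], 3) for i in range(len(ped)) if str(ped.breed[i]) == "AB"
)
print("composite blood classes (fraction of A ancestry -> count):")
for frac, n in sorted(blood.items()):
    print(f"  {frac:.3f}: {n}")
# 0.5 animals are F1-equivalent or fixed 50:50 crosses; 0.25/0.75 are the
# backcross classes a staged breeding program produces.
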