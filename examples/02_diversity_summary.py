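"""Inbreeding, coancestry and derived diversity statistics for one breed.

Simulates a closed studbook and summarizes its living population: mean
inbreeding F, mean coancestry C (self-pairs included), their per-generation
rates, the non-random mating degree alpha solving (1-F)=(1-C)(1-alpha), and
the genetic conservation index.  A positive alpha means mates are more
related than random pairs (line-breeding); near zero means random mating.
"""

import pedstruct as ps

cfg = ps.SimulationConfig(
    n_founders_per_breed=50, n_generations=6, missing_parent_rate=0.03, seed=42
)
ped = ps.simulate_purebred(cfg, breed="DEMO")
current = ps.subset_population(ped, "current")
s = ps.diversity_summary(current, seed=42)

print(f"living animals:        {s.n_reference}")
print(f"mean F:                {100 * s.mean_F:.2f} %")
print(f"mean C (with self):    {100 * s.mean_C:.2f} %")
print(f"mean dF per generation {100 * s.mean_dF:.2f} %  -> NeF = {ps.effective_size(s.mean_dF):.1f}")
print(f"mean dC per generation {100 * s.mean_dC:.2f} %  -> NeC = {ps.effective_size(s.mean_dC):.1f}")
print(f"alpha:                 {s.alpha:.4f}")
print(f"inbred / highly inbred {s.pct_inbred:.1f} % / {s.pct_highly_inbred:.1f} %  (F > 0 / F > 0.10)")
print(f"mean GCI:              {s.mean_GCI:.2f}")
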