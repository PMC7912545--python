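"""Population structure of a composite breed and its two ancestors.

Computes Wright's fixation indices, Nei minimum distances between the three
breeds and the UPGMA dendrogram.  The composite is built with majority-A
ancestry, so its Nei distance to breed A should be the smaller one and the
tree should join the composite with A first.
"""

import pedstruct as ps

cfg_a = ps.SimulationConfig(n_founders_per_breed=25, n_generations=4, seed=10)
cfg_b = ps.SimulationConfig(n_founders_per_breed=25, n_generations=4, seed=11)
scheme = [
    ps.CrossingStage("A", 1.0, "B", 0.0, 25),     # F1: 50% A
    ps.CrossingStage("A", 1.0, "AB", 0.5, 35),    # backcross: 75% A
    ps.CrossingStage("AB", 0.75, "AB", 0.75, 35), # inter se at 75% A
]
ped, frac = ps.simulate_composite(cfg_a, cfg_b, scheme, seed=12)

fs = ps.wright_f_statistics(ped)
print(f"FIS = {fs.fis:.4f}  FST = {fs.fst:.4f}  FIT = {fs.fit:.4f}")
print(f"identity check (1-FIT) - (1-FIS)(1-FST) = "
      f"{(1 - fs.fit) - (1 - fs.fis) * (1 - fs.fst):.2e}")

D = ps.nei_minimum_distance(ped)
print("\nNei minimum distance matrix:")
print(D.round(4))
print(f"\ncomposite closer to A? {D.loc['AB', 'A'] < D.loc['AB', 'B']}")
print("UPGMA tree (Newick):", ps.upgma_tree(D))
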