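"""Simulate a truth genome and an F2 mapping population.

Builds the default 7 x 100 cM genome (50 SSR-like markers per chromosome,
70 NB-LRR genes) and genotypes 92 F2 individuals, then checks that the
observed recombination fraction between one adjacent marker pair is close to
the map-function prediction for their true distance.
"""

from cucumap import CrossDesign, TruthConfig, cm_to_rf, estimate_rf, simulate_population, simulate_truth

truth = simulate_truth(TruthConfig(seed=1))
print(f"truth: {len(truth.chromosomes)} chromosomes, {len(truth.markers)} markers, "
      f"{len(truth.rgh_genes)} RGH genes, {len(truth.scaffolds)} scaffolds")

design = CrossDesign("F2", 92, seed=2, apply_suppression=False)
matrix = simulate_population(truth, design)
print(f"F2 matrix: {matrix.n_markers} markers x {matrix.n_individuals} individuals, "
      f"{(matrix.calls == -1).mean():.1%} missing")

m1, m2 = truth.markers[0], truth.markers[5]
d = m2.true_cm - m1.true_cm
est = estimate_rf(matrix.row(m1.id), matrix.row(m2.id), "F2")
print(f"marker pair {m1.id}/{m2.id}: true distance {d:.2f} cM "
      f"(Haldane r = {cm_to_rf(d, 'haldane'):.4f}), EM estimate r = {est.r_hat:.4f}, "
      f"LOD = {est.lod:.1f}")
print("The EM estimate should sit within sampling error of the Haldane",
      "recombination fraction, since crossovers are simulated without interference.")
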