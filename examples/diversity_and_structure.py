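"""Diversity statistics, pairwise F_ST, PCA, neighbour joining and AMOVA on a
simulated metapopulation.

The per-population table mirrors the usual summary layout: observed and
expected heterozygosity, nucleotide diversity, private alleles, F_IS and the
Weir-Goudet population-specific F_ST (beta).  High beta marks strongly drifted,
isolated populations."""

from lochgen import popstats, structure
from lochgen.sim import reference_config, simulate_metapopulation

G, popmap, env, truth = simulate_metapopulation(reference_config(7))

stats = popstats.per_pop_stats(G, popmap)
print("per-population summary (first five rows):")
print(stats.head().round(3).to_string())

fst = popstats.pairwise_fst(G, popmap)
print(f"\nmean pairwise Weir-Cockerham F_ST: {popstats.mean_pairwise_fst(fst):.3f} "
      "(the fraction of allele-frequency variance between population pairs)")

pca = structure.pca(G, n_axes=4)
print(f"PCA: EV1 explains {pca.percent_variance[0]:.2f}% of variance, "
      f"EV2 {pca.percent_variance[1]:.2f}%")

tree = structure.bootstrap_support(G, popmap, n_boot=100, seed=1)
print("\nneighbour-joining tree (bootstrap support on internal nodes):")
print(str(tree).strip())

groups = {ha: ("east" if ha.startswith("R1") else "west")
          for ha in set(popmap.df["hydrometric_area"])}
res = structure.amova(G, popmap, groups)
print("\nAMOVA percent of variance per stratum (sums to 100):")
print(res.percents.round(1).to_string())
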