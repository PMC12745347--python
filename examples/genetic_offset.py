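"""Genetic offset (genomic vulnerability) under a warming scenario.

Fits a gradient-forest-style turnover model on the climate-associated SNP
frequencies of each lake, shifts the temperature variables to build a future
scenario, and reports each lake's offset: the Euclidean distance between its
current and future positions in importance-transformed climate space.  Larger
offsets mean more predicted maladaptation under the scenario."""

from lochgen import gea, offset, units
from lochgen.io import CLIMATE_VARS
from lochgen.sim import reference_config, simulate_future_climate, simulate_metapopulation

G, popmap, env, truth = simulate_metapopulation(reference_config(7))
current = env.scenario("current")

mafs = offset.population_maf_matrix(G, popmap, by_lake=True)
adaptive = [s for s in mafs.columns if s in truth.adaptive_snp_ids]
kept = offset.low_variation_filter(mafs[adaptive])
retained, _ = gea.prune_collinear(current[CLIMATE_VARS])
model = offset.fit_turnover(mafs[kept], current[retained], n_trees=250, seed=7)
print("per-predictor turnover importance (top 3):")
print(model.total_importance.sort_values(ascending=False).head(3).round(4).to_string())

env2 = simulate_future_climate(env, {"bio1": 1.5, "bio5": 1.5, "bio10": 1.5}, "warming")
off = offset.genetic_offset(model, env2, "warming")
print(f"\ngenetic offset under +1.5 degree warming: "
      f"{off.min():.4f} (least exposed lake) to {off.max():.4f} (most exposed)")

reg = units.offset_regressions(off, env)
print("\nOLS of offset on geography (slope, R^2, p):")
print(reg.round(4).to_string())
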