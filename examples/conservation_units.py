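"""Lake-sensitivity scores and MU/ESU delineation for the packaged survey of
UK and Irish Arctic charr populations.

The composite sensitivity score (3 = least concern, 11 = highest concern) sums
bin scores for maximum depth, surface area and altitude: shallow, small,
low-lying lakes give least thermal refuge.  The delineation engine then merges
populations linked by documented translocations or shared close genetic
history and elevates units with ecotype or sole-Hydrometric-Area members to
Evolutionarily Significant Units."""

from lochgen import units
from lochgen.datasets import delineate_reference_units, load_population_summary

for name, depth, area, alt in [("small upland tarn", 6, 4, 8),
                               ("large deep valley loch", 150, 1800, 120)]:
    s = units.sensitivity_score(depth, area, alt)
    print(f"{name}: depth {s.depth_score} + area {s.area_score} + "
          f"altitude {s.altitude_score} = composite {s.composite}")

summary_table = load_population_summary()
print(f"\npackaged survey: {len(summary_table)} populations; observed "
      f"heterozygosity spans {summary_table['ho'].min():.3f}-{summary_table['ho'].max():.3f}")

computed, meta = delineate_reference_units()
counts = computed.summarize()
print(f"\ndelineation of the {len(meta)} Scottish populations: "
      f"{counts['esu_units']} ESU groups ({counts['esu_populations']} populations) "
      f"and {counts['mu_units']} MU groups ({counts['mu_populations']} populations)")
print("\nmulti-population units:")
for u in computed.units:
    if len(u.members) > 1:
        print(f"  {', '.join(u.members)} -> {u.unit_type} ({'; '.join(sorted(u.criteria))})")
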