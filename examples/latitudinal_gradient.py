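"""Latitudinal gradients, belts and quartile composition of assemblages.

Builds a synthetic dataset, summarizes assemblages per unit, fits the
quadratic richness-latitude curve and a lowess gradient of mean genus
age, assigns units to 10-degree latitudinal belts, and splits genera
into global age quartiles.
"""

from angiodiv import (SimulationConfig, assign_belts, belt_genus_union,
                      latitude_fit, quartile_partition, run_synthetic_pipeline,
                      unit_quartile_proportions)

ds, res = run_synthetic_pipeline(SimulationConfig(seed=11))
occupied = res.assemblage[res.assemblage["richness"] > 0]

quad = latitude_fit(occupied["richness"], occupied["lat"], kind="quadratic")
print(f"richness ~ lat + lat^2: r2 = {quad.r2:.2f}, curvature {quad.quad:.4f} "
      "(negative curvature = equator-peaked gradient)")

lw = latitude_fit(occupied["mean_age"], occupied["lat"].abs(), kind="lowess",
                  span=0.5)
print(f"lowess mean genus age: {lw.fitted[0]:.1f} Ma near the equator -> "
      f"{lw.fitted[-1]:.1f} Ma at |lat| {lw.x[-1]:.0f}")

assignment = assign_belts(ds.units)
belt_genera = belt_genus_union(res.incidence, assignment)
for belt in ("S5-N5", "N25-N35", "N45-N55"):
    if belt in belt_genera:
        print(f"belt {belt}: {len(belt_genera[belt])} genera")

labels = quartile_partition(res.profiles, "age")
props = unit_quartile_proportions(res.incidence, labels)
print("oldest-quartile share, 3 most tropical vs 3 most poleward units:")
by_lat = occupied["lat"].abs().sort_values()
print(f"  tropical {props.loc[by_lat.index[:3], 'q4'].mean():.2f} "
      f"vs poleward {props.loc[by_lat.index[-3:], 'q4'].mean():.2f}")
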