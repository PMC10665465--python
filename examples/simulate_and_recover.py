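"""Simulate one synthetic world and recover its latitudinal pattern.

Generates a 300-genus dated tree with rate-shift regimes, 60 geographic
units, and latitude-structured occurrences (old/slow genera toward the
equator, young/fast genera at high latitudes, equator-peaked richness),
then runs QC, assemblage summaries, and the spatially corrected tests.
"""

from angiodiv import SimulationConfig, run_synthetic_pipeline

ds, res = run_synthetic_pipeline(SimulationConfig(seed=1))

print(f"tree height: {ds.tree.height:.1f} Ma, {len(ds.tree)} genera, "
      f"{len(ds.events.events)} rate regimes")
print(f"occurrence records: {len(ds.occurrences)}; "
      f"presences after QC: {len(res.incidence)}")

t = res.richness_vs_netdiv
print(f"richness vs mean net diversification: r = {t.r:.3f}, "
      f"F-ratio = {t.f_ratio:.3f}, ESS = {t.ess:.1f}, p = {t.p:.4f}")
t = res.richness_vs_age
print(f"richness vs mean genus age:           r = {t.r:.3f}, "
      f"F-ratio = {t.f_ratio:.3f}, ESS = {t.ess:.1f}, p = {t.p:.4f}")
print("A negative rate correlation and positive age correlation mean the "
      "richest (tropical) assemblages hold old, slowly diversifying genera — "
      "the time-for-speciation signature the generator encodes.")
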