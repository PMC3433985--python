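"""Calibrate the waterfall clock and date each fall.

Regresses landlocked-vs-source genetic distance on waterfall height, converts
the slope C to an erosion rate E = R/C with the 3.8%/Myr substitution rate,
and divides heights by E to date every waterfall.
"""

import pandas as pd

from landlock import (
    DistanceModelSpec, SimulationConfig, calibrate_clock, group_mean_distance,
    load_waterfalls, pairwise_matrix, sanity_check_erosion, simulate_sequences,
)

cfg = SimulationConfig(seed=42)
table = simulate_sequences(cfg)
meta = table.meta
matrix = pairwise_matrix(table, DistanceModelSpec(model="TN93+G", gamma_shape=0.14))
br = list(meta.loc[meta["species"] == "BR", "individual_id"])

points = pd.DataFrame([
    {"name": name, "height_m": h,
     "distance": group_mean_distance(
         matrix,
         list(meta.loc[meta["population"] == f"YB{k:02d}", "individual_id"]),
         br)}
    for k, (name, h) in enumerate(zip(cfg.waterfall_names, cfg.heights_m), 1)
])

fit = calibrate_clock(points, rate_percent_per_myr=3.8)
reg = fit.regression
print(f"slope C = {fit.C:.6g} per m, intercept = {reg.intercept:.5f}, "
      f"r^2 = {reg.r_squared:.2f}, F_{reg.df[0]},{reg.df[1]} = {reg.F:.1f}")
print(f"erosion rate E = R/C = {fit.E_mm_yr:.2f} mm/yr "
      f"(truth {cfg.erosion_rate_true * 1000:.2f}) -> "
      f"{sanity_check_erosion(fit.E)['status']} the 0.3-1.0 mm/yr band")
print("\nestimated isolation ages (yr):")
for name, age in fit.ages.items():
    print(f"  {name:<18}{age:>10,.0f}")

# On the published data this chain gives E = 0.67 mm/yr and ages of roughly
# 11,000-88,000 yr; a single synthetic replicate scatters around the truth
# because each founder lineage carries random standing variation.
print("\npublished reference ages (packaged table):")
print(load_waterfalls().dropna().to_string(index=False))
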