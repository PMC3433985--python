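"""Occupancy and richness models for sites above and below waterfalls.

Presence of the landlocked species is perfectly separated by the waterfall
dummy (it occurs only above falls), so the logistic fits use Firth's
bias-reduced likelihood; model choice is exhaustive all-subsets AIC; species
richness uses a Poisson GLMM with a river-level random intercept.
"""

from landlock import SimulationConfig, all_subsets_aic, manova_wilks
from landlock.habitat import CONTINUOUS_FACTORS, glmm_fitter
from landlock.synthetic import simulate_habitat

sites = simulate_habitat(SimulationConfig(seed=42))

best, ranking = all_subsets_aic(sites, "presence")
print("occupancy (Firth logistic, all-subsets AIC over 10 factors):")
print(f"  best model: {list(best.predictors)}")
print(f"  waterfall coefficient: {best.coefficients.get('waterfall', 0.0):+.2f} "
      f"(truth +5 on the generator's scale)")
print(f"  AIC = {best.aic:.1f}, AUC = {best.auc:.2f}")

glmm_best, _ = all_subsets_aic(
    sites, "richness",
    predictor_pool=("waterfall", "water_depth_cm", "pebble_cm"),
    fitter=glmm_fitter(sites["river_id"].to_numpy()),
)
print("\nrichness (Poisson GLMM, river random intercept):")
print(f"  best model: {list(glmm_best.predictors)}")
print(f"  waterfall coefficient: "
      f"{glmm_best.coefficients.get('waterfall', 0.0):+.2f} (truth -1.3)")
print(f"  random-effect SD: {glmm_best.random_effect_sd:.2f} (truth 0.3)")

man = manova_wilks(sites.loc[:, list(CONTINUOUS_FACTORS)], sites["waterfall"])
print(f"\nMANOVA on the 9 continuous factors above vs below falls: "
      f"Wilks lambda = {man.wilks_lambda:.3f}, p = {man.p:.3f}")
# A non-significant MANOVA says the physical environment is comparable above
# and below falls: the waterfall itself, not habitat differences, explains
# the distribution.
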