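"""Richness, beta-diversity and allometric scaling of a cave metacommunity.

Generates a regional-census-scale synthetic dataset (141 springtail
species across 189 karst caves assembled by ecological drift), then
summarises local richness, proportional turnover beta_P = 1 - alpha/gamma,
endemism, and the power-law scaling of richness with cave size.
"""

import numpy as np

import cavecom as cc
from cavecom.diversity import diversity_summary, power_law_fit, site_richness

bundle = cc.synthetic.regional_census_dataset(seed=1)
matrix = bundle.matrix

summary = diversity_summary(matrix)
print(f"gamma (pool richness):   {summary.gamma} species, {matrix.n_sites} caves")
print(f"alpha per cave:          median {summary.alpha_median:.0f}, "
      f"mean {summary.alpha_mean:.2f}, range {summary.alpha_min}-{summary.alpha_max}")
print(f"beta_P = 1 - alpha/gamma: {summary.beta_p_mean:.2f} +- {summary.beta_p_se:.2f}")
print(f"endemics (single cave):  {cc.count_single_site_endemics(matrix)}")
print(f"species in > half caves: {cc.count_species_above_fraction(matrix, 0.5)}")
print(f"allometric slope z (gamma = alpha * N^z): {summary.z_slope:.2f}")

richness = site_richness(matrix)
for predictor in ("length_m", "depth_m", "altitude_m"):
    fit = power_law_fit(richness.to_numpy(),
                        bundle.metadata[predictor].to_numpy(),
                        n_perm=999, seed=2)
    print(f"log-log richness ~ {predictor}: exponent {fit.exponent:+.2f}, "
          f"r2 = {fit.r2:.2f}, permutation P = {fit.p_perm:.3f}")

print()
print("beta_P near 1 means nearly every cave hosts a distinct community;")
print("a z slope far above ~0.3 marks extreme spatial turnover for a")
print("terrestrial taxon.  Cave length (habitat size) explains the")
print("largest, still modest, share of richness; depth tracks length;")
print("altitude carries no planted effect, so its fit is noise-level.")
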