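"""Segregation and nestedness against equiprobable and proportional nulls.

Scores a drift-assembled metacommunity with the C-score (checkerboard
segregation) and NODF (nestedness), each standardized against 200
randomized matrices from the equiprobable (EE) and proportional (PP)
null models.  The contrast between the two nulls is the point: EE
ignores differences in cave capacity and species commonness, PP absorbs
them.
"""

import numpy as np

import cavecom as cc
from cavecom.cooccurrence import c_score, nodf

rng = np.random.default_rng(1)
weights = np.exp(1.5 * rng.normal(size=40))          # skewed commonness
capacities = np.clip(np.round(np.exp(
    np.log(5) + 0.7 * rng.normal(size=60))).astype(int), 1, 40)
matrix = cc.synthetic.gen_drift_assembly(weights, capacities, seed=rng)
print(f"matrix: {matrix.n_species} species x {matrix.n_sites} sites, "
      f"fill {matrix.fill}")

for model in ("EE", "PP"):
    for name, metric in (("C-score", c_score), ("NODF", nodf)):
        result = cc.metric_ses(matrix, metric, model, reps=200,
                               seed=rng.integers(2**31))
        print(f"{name:8s} under {model}: obs {result.observed:8.2f}  "
              f"null {result.null_mean:8.2f} +- {result.null_sd:6.2f}  "
              f"SES {result.ses:+7.2f}  (p_lo {result.p_lower:.3f}, "
              f"p_hi {result.p_upper:.3f})")

print()
print("Negative C-score SES / positive NODF SES under EE: passive")
print("sampling makes common species co-occur, which the equiprobable")
print("null reads as aggregation and nestedness.  The PP null, built")
print("from the observed marginals, absorbs most of that signal --")
print("|SES| shrinks by an order of magnitude.  |SES| > 1.96 marks a")
print("two-sided 5% deviation.")
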