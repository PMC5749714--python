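# cavecom

Null-model analysis of community incidence data from isolated habitats —
built around the question of whether cave-dwelling springtail (Collembola)
assemblages are shaped by competition and habitat filtering or by neutral
colonisation dynamics (ecological drift).

Caves are natural island laboratories: isolated, environmentally stable,
and colonised by poorly dispersing specialists.  Given a binary species ×
cave presence–absence matrix, cave characteristics (location, length,
depth, altitude), and a ranked taxonomic classification, `cavecom` asks
three questions a community ecologist would put to such data:

1. **Is local richness depauperate and turnover high?**
   Proportional β-diversity β_P = 1 − α/γ (α = mean per-cave richness,
   γ = pool richness), endemism counts, and the allometric scaling
   γ = α·N^z.
2. **Does species co-occurrence deviate from neutral expectation?**
   The C-score — the mean number of checkerboard units
   CU_ij = (r_i − S_ij)(r_j − S_ij) over species pairs — measures
   segregation; NODF (nestedness by overlap and decreasing fill, 0–100)
   measures nestedness.  Both are standardized against randomization
   ensembles: SES = (Obs − Exp)/SD_Exp, with |SES| > 1.96 a two-sided 5%
   deviation.  Three null models are provided: **EE** (equiprobable cell
   placement, preserving total fill F), **PP** (placement probability ∝
   row total × column total — a neutral model without dispersal
   limitation), and **FF** (checkerboard-swap chains preserving all
   marginals exactly).  A longitude-sorted shifting-window analysis
   tracks how the SES values vary with regional richness.
3. **Is community membership taxonomically non-random?**
   With no molecular phylogeny, relatedness is read off the ranked
   classification: the distance between two species is the number of
   taxon nodes on the tree path between them.  The net relatedness index
   NRI is the SES of a cave's mean pairwise distance (MPD) against
   richness-matched random pool draws — positive = overdispersed
   (competition-like), negative = clustered (filtering-like).

An inference layer ties the pieces together: main-effects general linear
models reporting partial η² = SS_effect/(SS_effect + SS_error) with the
dominant spatial eigenvector (EV1) as covariate, significance
pre-screening of pairwise co-occurrences, and a trait-identity ANOVA on
the screened pairs.  A synthetic-data module generates incidence
matrices (random, nested, checkerboard, drift-assembled), 9-rank
taxonomies, cave metadata and categorical traits, so every analysis runs
end-to-end with no external data.

## Worked example

```python
import cavecom as cc
from cavecom.diversity import diversity_summary

bundle = cc.synthetic.regional_census_dataset(seed=1)   # 141 species x 189 caves
s = diversity_summary(bundle.matrix)
print(f"median alpha {s.alpha_median:.0f}, beta_P {s.beta_p_mean:.2f}, z {s.z_slope:.2f}")

windows = cc.make_windows(bundle.metadata, window_size=20, n_windows=9)
table, regs = cc.window_metrics(bundle.matrix, windows, models=("EE",),
                                reps=200, seed=2)
print(regs[["metric", "slope", "p_perm"]])
```

prints

```
median alpha 4, beta_P 0.96, z 0.62
   metric     slope  p_perm
0  cscore -0.392388   0.036
1    nodf  0.276631   0.115
```

Median cave richness 4 against a 141-species pool gives β_P = 0.96 —
nearly every cave hosts a distinct community.  Across the nine
longitude windows, segregation (C-score SES) falls and nestedness
(NODF SES) rises with window richness: the signature of passive
sampling from a common pool rather than competitive structuring.
The `examples/` directory holds one narrative script per capability
(diversity partitioning, co-occurrence nulls, taxonomic relatedness,
shifting windows, trait screening + GLMs); each prints its numbers with
a line on what they mean.

## Layout

- `src/cavecom/community_data.py` — incidence matrix, metadata, taxonomy
  and trait containers; readers, sampling-intensity rules, validation
- `src/cavecom/diversity.py` — richness, β_P, endemism, allometric fits
- `src/cavecom/cooccurrence.py` — C-score, NODF, per-pair SES tables
- `src/cavecom/null_models.py` — EE/PP/FF randomizers, ensembles, SES
- `src/cavecom/relatedness.py` — taxonomic distances, MPD, NRI
- `src/cavecom/spatial.py` — shifting windows, EV1 spatial covariate
- `src/cavecom/inference.py` — partial-η² GLMs, screening, trait ANOVA
- `src/cavecom/synthetic.py` — data generators and the regional-census preset

See `docs/methods.md` for the statistical conventions, generator design
and known limitations.
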