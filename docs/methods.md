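# Methods

This note records the statistical conventions, numerical choices and
design decisions behind `cavecom`, and what the synthetic-data tests do
and do not show about real data.

## Data model

The analysis object is a binary species × site incidence matrix with
row totals r_i (species occupancy), column totals c_j (site richness)
and fill F = Σ entries.  Counts binarize on input (>0 → 1): every
metric here is defined on presence–absence.  Caves carry longitude,
latitude, length (m, >0), depth (m, ≥0), altitude (m a.s.l.) and a
visit count mapped to a sampling-intensity class (1–3 visits → class 1,
4–6 → 2, 7–9 → 3, 10–12 → 4; counts outside 1–12 are rejected rather
than clamped, since the classification is defined only there).  Sites
surveyed fewer than `min_visits` (default 3) times can be filtered out;
species rows emptied by that filter are dropped and reported, so γ is
always the pool of the analysed matrix.  Missing length/depth/altitude
values are permitted and excluded pairwise in regressions.

## Co-occurrence metrics

**C-score.**  For a species pair, CU = (r_i − S)(r_j − S) with S the
count of jointly occupied sites; this equals the number of 2×2
checkerboard submatrices the pair forms (verified exactly against
exhaustive enumeration in the tests).  The matrix-level score is the
plain mean of CU over unordered species pairs — no division by r_i·r_j
or by site pairs — which is the only normalization consistent with
"count of checkerboard units".  Since every SES standardizes by the
null SD, any constant normalization would cancel there anyway.

**NODF.**  For each pair of rows with *unequal* row totals, the paired
score is 100 × (shared sites)/(smaller total); tied totals contribute 0
("decreasing fill" fails in both orientations).  Same over column
pairs; NODF is the sum over all row and column pairs divided by the
total pair count.  Marginal totals, not physical order, decide the
richer member, making the score permutation-invariant.

## Null models and SES

All ensembles default to 200 replicates (configurable), with per-rep
seeds spawned from one seed sequence, so an ensemble is reproducible
from (model, reps, seed).

- **EE** places F occurrences uniformly among distinct cells.
- **PP** places F occurrences without replacement with cell probability
  ∝ r_i·c_j, implemented by exponential-sort weighted sampling, which
  is equivalent to sequential draws with renormalization.  Fill is
  exact; marginals are preserved in expectation.
- **FF** runs a checkerboard-swap chain: random 2×2 submatrices of the
  form {{1,0},{0,1}} are flipped, conserving all marginals exactly.
  Burn-in is 10×F successful swaps and thinning F swaps between saved
  matrices (common practice for swap chains; both configurable).  An
  attempt cap (1000× the target) turns a near-frozen matrix into a
  warning rather than a hang.

**Occupancy conditioning.**  By default EE and PP resample whole
matrices until no row or column is empty (cap 10,000 attempts), keeping
the conditional distribution clean: an empty row or column would change
the species pool or site set mid-analysis.  This constraint is only
reachable when expected empties per draw are ~1 or fewer.  Sparse
submatrices — a 20-cave window where the mean species occupies ~2 sites
— put the acceptance probability around e^(−7) per attempt, so the
window analysis uses unconditional ensembles (`require_no_empty=False`),
which is also how the classical equiprobable and proportional nulls are
defined.  Both metrics handle empty rows gracefully (they contribute
zero checkerboards and zero NODF overlap).

**SES.**  SES = (Obs − mean_null)/SD_null with the n−1 SD (null values
are a sample from the null distribution); zero null SD yields NaN SES
with tail probabilities still reported.  Empirical tails use the
add-one rule (b+1)/(n+1), so the smallest attainable p with 200 nulls
is 1/201 ≈ 0.005 and p is never 0.

Self-calibration (tested): scoring EE-generated matrices against EE
ensembles gives SES with |mean| < 0.15, SD in [0.8, 1.2], and ~5%
beyond ±1.96.  On drift-assembled matrices with skewed marginals the
EE SES is an order of magnitude larger than the PP SES — EE reads the
marginal heterogeneity itself as structure, PP absorbs it.  Note that
PP SES on drift matrices is *not* centred at zero (measured ≈ −4):
drift assembly fixes each site's richness exactly while PP preserves
marginals only in expectation, so the observed C-score sits
systematically below the PP null mean.  PP is a variance-absorbing
reference, not an exact generative inverse.

## Taxonomic relatedness

The distance between two species is the number of taxon nodes on the
classification-tree path between them: every named rank node passed on
the descent from the lowest common taxon to each species, plus that
common taxon once, with the species tips excluded and absent ranks
contributing no node.  Internal ranks run order → suborder →
superfamily → family → subfamily → tribe → genus → subgenus; the
species is the tip.  Two species sharing everything through the
subgenus are 1 step apart; two fully classified species from different
orders, each with seven named ranks (no suborder), are 7 + 7 + 1 = 15
steps apart, the convention's calibration case.  When two lineages
share no named rank the common taxon is the implicit class root.

NRI is the SES of a community's mean pairwise distance against
richness-matched draws from the pool, *without* the sign flip some
authors apply: positive NRI = overdispersion.  Null draws are
equiprobable (not occupancy-weighted) from the pool, operationalized as
all species of the analysed matrix; the rep default is 1000 (cheap, and
stabilizes the SD estimate; the co-occurrence nulls' 200 is a separate
knob).  Communities of richness < 2 are undefined and skipped.

## Spatial analysis

Windows: sites sorted by longitude ascending (ties: latitude, then site
id, for determinism), the first `n_windows × window_size` sites cut
into consecutive blocks, surplus dropped from the high-longitude end.
Defaults 9 × 20 suit a ~189-site census.  Per window the submatrix
(emptied species rows dropped) is scored with both metrics against each
requested null model, and window SES is regressed on pooled richness
with a permutation p-value.

EV1: squared Euclidean distances on raw decimal degrees (the study
region is small enough that great-circle correction is cosmetic;
`method="raw"` gives the dominant eigenvector of the unsquared distance
matrix as an alternative), double-centred, first eigenvector scaled by
√eigenvalue — the principal-coordinate construction, equivalent to the
leading PCA axis of the coordinates.  Orientation is fixed by positive
correlation with longitude so the sign is deterministic.

## Inference layer

Partial η² = SS_term/(SS_term + SS_residual), with SS_term computed by
term deletion from the main-effects fit (Type III for a design without
interactions).  Each table column is one term; categorical columns
expand to one multi-df dummy block.  Signs are reported for single-df
terms only; significance stars: * <0.05, ** <0.01, *** <0.001.
Rank-deficient designs raise, naming the term set.

Pair screening keeps pairs with either empirical tail below α = 0.05
and tags the direction.  On equiprobable null data the retained share
is near-nominal: two 5% tails would give ~10%, the discreteness of the
CU null distribution pulls it down, and 2–12% per matrix is what the
calibration measures.  The trait ANOVA codes each pair 1/0 for
trait-level identity and treats pairs as independent observations —
pairs share species, so these p-values are anti-conservative; treat the
η² ranking, not the p-values, as the interpretable output.  Permutation
regressions shuffle the response and count permuted r² ≥ observed with
the add-one rule.

## Synthetic data

Generators are deterministic under a fixed seed and always emit bundles
passing cross-table validation.  Matrix generators condition on no
empty rows/columns like the null engines (disable only to exercise
error paths).

- `gen_random_matrix`: uniform occupancy at fixed fill (the EE
  generative model).
- `gen_nested_matrix`: site j holds the top-k_j ranked species, k
  decaying as a power curve (steepness); noise flips a fraction of
  cells.  With noise 0 and n_sites ≤ n_species the fills are distinct
  and NODF is exactly 100.
- `gen_checkerboard_matrix`: complementary species pairs on random site
  halves; within-pair CU = (n_sites/2)², maximal given the marginals.
- `gen_drift_assembly`: each site draws its capacity of species without
  replacement with probability ∝ pool weight — passive sampling / mass
  effects.  Under skewed weights some species are drawn nowhere; since
  an observed pool is by definition the set of recorded species, the
  default grants each such species one occurrence at a
  capacity-weighted site (they become single-site endemics, as the
  rarest real species are).  `reject` and `drop` modes exist.
- `gen_taxonomy`: recursive random partition of the species set over
  the eight internal ranks with per-rank branching factors; labels are
  globally unique so the tree is consistent by construction.

**The regional-census preset** (`regional_census_dataset`) is the package's
reference study condition: 141 species × 189 caves assembled by drift.
Per-cave capacity is lognormal with median 4 and total log-SD 0.8,
giving mean richness ≈ 5.6, maxima in the 20–45 range, β_P ≈ 0.96 and
z ≈ 0.62.  Part of the log-variance is structured: a ln(length) loading
of 0.288 (⇒ log–log richness–length r² ≈ 0.13 in expectation) and a
longitude loading of 0.30 (an east–west richness gradient, so the
shifting windows span a richness range as a real region does); depth is
log-correlated with length at ρ = 0.68 (⇒ depth r² ≈ 0.06).  Species
weights are lognormal with log-SD 1.5, yielding ~50 single-cave
endemics and at most a species or two in more than half the caves.
Visits are uniform on 3–12: the matrix represents a census after
under-surveyed caves were excluded.

What passing tests on these data show — and what they do not: the
generators reproduce the *marginal and null-model structure* of a
regional cave census (richness distribution, turnover, occupancy skew,
drift geometry), so they validate the metrics, the null machinery and
the qualitative richness trends.  They contain no real spatial
autocorrelation beyond the planted longitude gradient, no habitat
filtering, no phylogenetic signal in occupancy, and no observation
error; tests passing here say nothing about whether those forces act in
any real system — that is precisely the question the package is meant
to ask of real data.

A window-level caveat found during development: the monotone
"NODF SES rises with window richness" trend is a property of
drift-style assembly, not of nestedness per se — on deterministic
threshold-nested matrices the richest windows saturate and the trend
vanishes.  The window tests therefore use drift assemblies.

## Problem sizes

Default test and example runs use 200-rep ensembles at up to 141 × 189
(whole-matrix metrics), 20-site windows, and 1000-rep NRI draws; the
full suite runs in about half a minute on one core.  All knobs (reps,
burn-in, thinning, window geometry) scale up for production analyses.

## Known limitations

- No abundance-weighted or analytic null expectations; inference is
  purely resampling-based.
- The FF chain's mixing is not diagnosed; burn-in/thinning defaults are
  conventional, and uniformity over the marginal-preserving set is not
  certified (the tests check support on a small enumerable case).
- Taxonomic distances are step counts, not branch lengths; NTI /
  nearest-taxon statistics and tree-file ingestion are out of scope.
- The trait ANOVA inherits the non-independence of shared-species
  pairs, as noted above.
- β-diversity is the proportional partition only; no Sørensen/Simpson
  decompositions.
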