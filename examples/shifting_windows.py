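"""Shifting-window co-occurrence analysis along the longitude gradient.

Sorts the 189 caves by longitude, cuts nine non-overlapping windows of
20 caves, and scores each window's submatrix with C-score and NODF SES
against 200-rep equiprobable ensembles; then regresses the SES values on
pooled window richness with a permutation test.
"""

import cavecom as cc

bundle = cc.synthetic.regional_census_dataset(seed=1)
windows = cc.make_windows(bundle.metadata, window_size=20, n_windows=9)
print(f"9 windows x 20 caves, {len(windows.unassigned)} caves unassigned "
      f"at the high-longitude end")

table, regressions = cc.window_metrics(bundle.matrix, windows, models=("EE",),
                                       reps=200, seed=2, n_perm=999)
print(table[["window_index", "pooled_richness",
             "cscore_ses_EE", "nodf_ses_EE"]].round(2).to_string(index=False))
print()
for _, row in regressions.iterrows():
    print(f"{row['metric']:6s} SES ~ richness: slope {row['slope']:+.3f}, "
          f"r2 = {row['r2']:.2f}, permutation P = {row['p_perm']:.3f}")
print()
print("Species-richer windows look more nested (NODF slope > 0) and less")
print("segregated (C-score slope < 0) relative to the equiprobable null --")
print("the signature of passive sampling from a common pool rather than")
print("competitive structuring.")
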