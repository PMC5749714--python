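"""Taxonomic step distances and per-cave net relatedness (NRI).

Builds the step-distance matrix from a ranked classification — the
distance between two species is the number of taxon nodes on the tree
path between them — and computes each cave's NRI: the standardized
effect size of its mean pairwise distance against richness-matched
random draws from the species pool (positive = overdispersed).
"""

import pandas as pd

import cavecom as cc
from cavecom.community_data import TaxonomyTable

# two fully classified springtails from different orders (no suborder)
example = TaxonomyTable(pd.DataFrame(
    {
        "order": ["Poduromorpha", "Entomobryomorpha"],
        "superfamily": ["Neanuroidea", "Entomobryoidea"],
        "family": ["Neanuridae", "Lepidocyrtidae"],
        "subfamily": ["Pseudachorutinae", "Lepidocyrtinae"],
        "tribe": ["Pseudachorutini", "Lepidocyrtini"],
        "genus": ["Anurida", "Lepidocyrtus"],
        "subgenus": ["Anurida", "Lanocyrtus"],
    },
    index=["Anurida subarctica", "Lepidocyrtus selvaticus"],
))
steps = cc.taxonomic_distance("Anurida subarctica", "Lepidocyrtus selvaticus",
                              example)
print(f"Anurida (Anurida) subarctica vs Lepidocyrtus (Lanocyrtus) selvaticus:"
      f" {steps} steps")
print("(7 rank nodes down each lineage from the shared root, plus the root)")

bundle = cc.synthetic.regional_census_dataset(seed=1)
dmatrix = cc.distance_matrix(bundle.taxonomy)
table = cc.nri_per_site(bundle.matrix, dmatrix, reps=1000, seed=2)
print(f"\nNRI computed for {len(table)} caves with >= 2 species")
print(table[["site_id", "richness", "mpd_obs", "nri"]].head(5)
      .to_string(index=False))
frac = (table["nri"].abs() >= 2).mean()
print(f"\ncaves with |NRI| >= 2: {frac:.1%}")
print("Near-nominal 5%: drift-assembled communities carry no taxonomic")
print("signal -- neither the clustering expected from habitat filtering")
print("nor the overdispersion expected from competitive exclusion.")
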