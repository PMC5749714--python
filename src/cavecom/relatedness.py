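"""Taxonomic step distances and the net relatedness index (NRI).

With no molecular phylogeny available, relatedness is read off the ranked
classification: the distance between two species is the number of taxon
nodes on the tree path between them — every rank node passed on the way
down from the lowest common taxon to each species, plus that common taxon
itself, with the two species tips excluded and absent ranks contributing
no node.  Two species sharing everything down to the subgenus are 1 step
apart (only the subgenus lies between them); species from different
orders that each carry 7 named ranks are 7 + 7 + 1 = 15 steps apart.

NRI is the standardized effect size of a community's mean pairwise
distance (MPD) against richness-matched random draws from the species
pool.  Following the SES convention directly (no sign flip), positive
NRI means taxonomic overdispersion — members more distantly related than
a random pool sample — and negative NRI means clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from cavecom.community_data import IncidenceMatrix, TaxonomyTable


def taxonomic_distance(species_a: str, species_b: str,
                       taxonomy: TaxonomyTable) -> int:
    """Step distance between two species through the taxonomy tree."""
    species_a, species_b = str(species_a), str(species_b)
    if species_a == species_b:
        taxonomy.path(species_a)  # raises if unknown
        return 0
    path_a = taxonomy.path(species_a)
    path_b = taxonomy.path(species_b)
    shared = 0
    for node_a, node_b in zip(path_a, path_b):
        if node_a != node_b:
            break
        shared += 1
    # nodes strictly between each tip and the lowest common taxon, plus
    # the common taxon itself (the root of the classification when the
    # two lineages share no named rank)
    return (len(path_a) - shared) + (len(path_b) - shared) + 1


def distance_matrix(taxonomy: TaxonomyTable, species=None) -> DistanceMatrix:
    """Full symmetric matrix of pairwise taxonomic step distances."""
    ids = [str(s) for s in (species if species is not None else taxonomy.species_ids)]
    paths = [taxonomy.path(s) for s in ids]
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pa, pb = paths[i], paths[j]
            shared = 0
            for node_a, node_b in zip(pa, pb):
                if node_a != node_b:
                    break
                shared += 1
            values[i, j] = values[j, i] = (len(pa) - shared) + (len(pb) - shared) + 1
    return DistanceMatrix(values, ids)


def mpd(community, dmatrix: DistanceMatrix) -> float:
    """Mean pairwise distance among the members of one community."""
    ids = [str(s) for s in community]
    if len(set(ids)) < 2:
        raise ValueError("MPD needs a community of at least 2 species")
    sub = dmatrix.filter(ids).data
    iu = np.triu_indices(sub.shape[0], k=1)
    return float(sub[iu].mean())


def _mpd_from_indices(data: np.ndarray, idx: np.ndarray) -> float:
    sub = data[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    return float(sub[iu].mean())


@dataclass
class NriResult:
    site_id: str
    richness: int
    mpd_obs: float
    null_mean: float
    null_sd: float
    nri: float
    p_lower: float
    p_upper: float
    reps: int


def nri(community, pool, dmatrix: DistanceMatrix, reps: int = 1000, seed=None,
        site_id: str = "") -> NriResult:
    """NRI of one community against richness-matched pool draws.

    Null communities are drawn uniformly without replacement from the
    pool (equiprobable, not occupancy-weighted).  Zero null variance
    (e.g. community == pool) yields NaN NRI with tail probabilities
    still reported.
    """
    community = [str(s) for s in community]
    pool = [str(s) for s in pool]
    if not set(community) <= set(pool):
        raise ValueError("community must be a subset of the pool")
    k = len(community)
    if k < 2:
        raise ValueError("NRI needs a community of at least 2 species")
    index = {s: i for i, s in enumerate(dmatrix.ids)}
    data = dmatrix.data
    obs = _mpd_from_indices(data, np.array([index[s] for s in community]))
    pool_idx = np.array([index[s] for s in pool])
    rng = np.random.default_rng(seed)
    null = np.empty(reps)
    for r in range(reps):
        null[r] = _mpd_from_indices(data, rng.choice(pool_idx, size=k, replace=False))
    mean = float(null.mean())
    sd = float(null.std(ddof=1))
    z = (obs - mean) / sd if sd > 0 else float("nan")
    p_upper = (int((null >= obs).sum()) + 1) / (reps + 1)
    p_lower = (int((null <= obs).sum()) + 1) / (reps + 1)
    return NriResult(site_id, k, obs, mean, sd, z, p_lower, p_upper, reps)


def nri_per_site(matrix: IncidenceMatrix, dmatrix: DistanceMatrix,
                 reps: int = 1000, seed=None, pool=None) -> pd.DataFrame:
    """NRI for every site of an incidence matrix.

    The pool defaults to all species of the analysed matrix.  Sites with
    richness < 2 are skipped (NRI undefined there).
    """
    pool = list(pool) if pool is not None else list(matrix.species_ids)
    seed_seq = np.random.SeedSequence(seed)
    rows = []
    species = np.asarray(matrix.species_ids)
    children = seed_seq.spawn(matrix.n_sites)
    for j, site in enumerate(matrix.site_ids):
        members = species[matrix.values[:, j] == 1]
        if members.size < 2:
            continue
        res = nri(members, pool, dmatrix, reps=reps,
                  seed=np.random.default_rng(children[j]), site_id=site)
        rows.append(res.__dict__)
    return pd.DataFrame(rows)
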