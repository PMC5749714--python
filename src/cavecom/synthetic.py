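"""Synthetic metacommunities: incidence matrices with controllable
structure, ranked taxonomies, cave metadata, and categorical traits.

Every generator is deterministic under a fixed seed and emits data that
pass :func:`cavecom.community_data.validate_dataset`.  Matrix generators
condition on no empty rows or columns (matching the null engines) unless
``allow_degenerate`` is set, which exists only so error paths can be
exercised deliberately.

The ``regional_census`` preset bundles everything into one drift-assembled
141-species x 189-cave metacommunity whose marginal structure mimics a
regional karst-cave census: median cave richness 4 (range ~1-30, mean
~5.6, hence proportional turnover beta_P ~= 0.96), lognormal cave
lengths and depths, a mild east-west richness gradient, and a heavily
skewed species-occupancy distribution with many single-cave endemics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cavecom.community_data import RANKS, IncidenceMatrix, TaxonomyTable
from cavecom.null_models import _check_feasible, _place_uniform, _rejection_sample


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _labels(prefix: str, n: int) -> tuple[str, ...]:
    width = len(str(n))
    return tuple(f"{prefix}{i + 1:0{width}d}" for i in range(n))


def _wrap(values: np.ndarray) -> IncidenceMatrix:
    return IncidenceMatrix(values, _labels("sp", values.shape[0]),
                           _labels("cave", values.shape[1]))


# ---------------------------------------------------------------------------
# incidence matrices


def gen_random_matrix(n_species: int, n_sites: int, fill: int,
                      seed=None, allow_degenerate: bool = False) -> IncidenceMatrix:
    """Equiprobable occupancy conditional on no empty row/column."""
    rng = _rng(seed)
    shape = (n_species, n_sites)
    if allow_degenerate:
        return _wrap(_place_uniform(shape, fill, rng))
    _check_feasible(shape, fill)
    values = _rejection_sample(lambda: _place_uniform(shape, fill, rng),
                               shape, fill)
    return _wrap(values)


def gen_nested_matrix(n_species: int, n_sites: int, steepness: float = 1.0,
                      noise: float = 0.0, seed=None) -> IncidenceMatrix:
    """Nested metacommunity: site j holds the top k_j ranked species.

    With ``noise = 0`` the matrix is a perfectly nested threshold matrix
    (poorer sites are strict subsets of richer ones); with
    ``n_sites <= n_species`` the site richnesses are strictly
    decreasing, the distinct-fill stair on which NODF is exactly 100.
    ``steepness`` bends the richness decay (power curve); ``noise``
    flips that fraction of cells at random, degrading nestedness
    monotonically in expectation.
    """
    if steepness <= 0:
        raise ValueError("steepness must be > 0")
    if not 0 <= noise < 1:
        raise ValueError("noise must be in [0, 1)")
    rng = _rng(seed)
    j = np.arange(n_sites)
    frac = 1.0 - j / n_sites
    k = np.maximum(1, np.round(n_species * frac ** steepness).astype(int))
    values = (np.arange(n_species)[:, None] < k[None, :]).astype(np.int8)
    if noise > 0:
        n_cells = values.size
        n_flip = int(round(noise * n_cells))
        for _ in range(10_000):
            flipped = values.copy().ravel()
            idx = rng.choice(n_cells, size=n_flip, replace=False)
            flipped[idx] = 1 - flipped[idx]
            flipped = flipped.reshape(values.shape)
            if flipped.sum(axis=1).all() and flipped.sum(axis=0).all():
                values = flipped
                break
        else:
            raise RuntimeError("could not add noise without emptying a row/column")
    return _wrap(values)


def gen_checkerboard_matrix(n_pairs: int, n_sites: int, seed=None) -> IncidenceMatrix:
    """Perfectly segregated metacommunity of complementary species pairs.

    Each pair splits the sites into two random halves: one member
    occupies one half, its partner the complement, so every within-pair
    2x2 submatrix is a checkerboard (CU = (n_sites/2)^2, the maximum
    attainable given the marginals).
    """
    if n_sites % 2:
        raise ValueError("n_sites must be even")
    rng = _rng(seed)
    half = n_sites // 2
    values = np.zeros((2 * n_pairs, n_sites), dtype=np.int8)
    for p in range(n_pairs):
        sites = rng.permutation(n_sites)
        values[2 * p, sites[:half]] = 1
        values[2 * p + 1, sites[half:]] = 1
    return _wrap(values)


def gen_drift_assembly(pool_weights, site_capacities, seed=None,
                       empty_species: str = "augment") -> IncidenceMatrix:
    """Passive-sampling (mass-effects) assembly from a weighted pool.

    Site j draws ``site_capacities[j]`` species without replacement with
    probability proportional to the pool weights — ecological drift
    without dispersal limitation: common species recur everywhere, rare
    ones sprinkle at random.  Under skewed weights some pool species may
    be drawn nowhere; since an observed species pool consists by
    definition of species recorded at least once, the default
    (``empty_species='augment'``) grants each such species one occurrence
    at a capacity-weighted random site — these become single-site
    endemics, as the rarest species in real censuses are.
    ``'reject'`` regenerates the whole matrix instead (only viable for
    mild skew); ``'drop'`` removes the unrecorded species.
    """
    weights = np.asarray(pool_weights, dtype=float)
    capacities = np.asarray(site_capacities, dtype=int)
    if (weights <= 0).any() or (capacities <= 0).any():
        raise ValueError("weights and capacities must be positive")
    if capacities.max() > weights.size:
        raise ValueError("site capacity exceeds pool size")
    if empty_species not in ("augment", "reject", "drop"):
        raise ValueError(f"unknown empty_species mode {empty_species!r}")
    rng = _rng(seed)
    n_species, n_sites = weights.size, capacities.size

    def place():
        values = np.zeros((n_species, n_sites), dtype=np.int8)
        for j, cap in enumerate(capacities):
            keys = rng.exponential(size=n_species) / weights
            chosen = np.argpartition(keys, cap - 1)[:cap]
            values[chosen, j] = 1
        return values

    if empty_species == "reject":
        for _ in range(10_000):
            values = place()
            if values.sum(axis=1).all():
                return _wrap(values)
        raise RuntimeError("could not assemble a matrix with no empty species "
                           "row; weights may be too skewed for rejection")
    values = place()
    empty = np.flatnonzero(values.sum(axis=1) == 0)
    if empty.size and empty_species == "augment":
        p = capacities / capacities.sum()
        for i in empty:
            values[i, rng.choice(n_sites, p=p)] = 1
    elif empty.size:
        values = values[values.sum(axis=1) > 0]
    return _wrap(values)


# ---------------------------------------------------------------------------
# taxonomy / metadata / traits


def gen_taxonomy(n_species: int, children_per_rank=2, seed=None,
                 species_ids=None) -> TaxonomyTable:
    """Random 9-rank taxonomy (8 internal ranks + species tips).

    Starting from a single root group, the species set is recursively
    partitioned: at each rank every current group splits into up to
    ``children_per_rank`` subgroups (an int, or one int per rank).
    Taxon labels are globally unique, so the implied tree is consistent
    by construction.
    """
    rng = _rng(seed)
    if species_ids is None:
        species_ids = _labels("sp", n_species)
    species_ids = tuple(map(str, species_ids))
    if np.isscalar(children_per_rank):
        children = [int(children_per_rank)] * len(RANKS)
    else:
        children = [int(c) for c in children_per_rank]
        if len(children) != len(RANKS):
            raise ValueError(f"children_per_rank needs {len(RANKS)} entries")
    groups = {0: list(range(n_species))}
    counter = 0
    table = {rank: [None] * n_species for rank in RANKS}
    for rank, c in zip(RANKS, children):
        new_groups = {}
        for members in groups.values():
            assignment = rng.integers(0, max(c, 1), size=len(members))
            for bucket in np.unique(assignment):
                counter += 1
                label = f"{rank}_{counter}"
                sub = [m for m, a in zip(members, assignment) if a == bucket]
                new_groups[counter] = sub
                for m in sub:
                    table[rank][m] = label
        groups = new_groups
    frame = pd.DataFrame(table, index=list(species_ids))
    return TaxonomyTable(frame)


def gen_cave_metadata(n_sites: int, seed=None,
                      length_logmean: float = np.log(200.0),
                      length_logsd: float = 1.2,
                      depth_logmean: float = np.log(20.0),
                      depth_logsd: float = 1.0,
                      depth_length_corr: float = 0.68,
                      altitude_range: tuple = (150.0, 1400.0),
                      lon_range: tuple = (21.0, 29.0),
                      lat_range: tuple = (43.6, 48.3),
                      visits_range: tuple = (3, 12),
                      site_ids=None) -> pd.DataFrame:
    """Cave metadata with right-skewed sizes and boxed coordinates.

    Lengths and depths are lognormal (depth log-correlated with length,
    as deeper caves tend to be longer); altitudes and coordinates are
    uniform in their ranges; visit counts are uniform integers within
    ``visits_range`` (a sub-range of the 1-12 classification domain).
    """
    rng = _rng(seed)
    if site_ids is None:
        site_ids = _labels("cave", n_sites)
    z_len = rng.normal(size=n_sites)
    z_dep = depth_length_corr * z_len + \
        np.sqrt(1 - depth_length_corr ** 2) * rng.normal(size=n_sites)
    frame = pd.DataFrame({
        "longitude": rng.uniform(*lon_range, size=n_sites),
        "latitude": rng.uniform(*lat_range, size=n_sites),
        "length_m": np.exp(length_logmean + length_logsd * z_len),
        "depth_m": np.exp(depth_logmean + depth_logsd * z_dep),
        "altitude_m": rng.uniform(*altitude_range, size=n_sites),
        "visits": rng.integers(visits_range[0], visits_range[1] + 1, size=n_sites),
    }, index=list(site_ids))
    frame.index.name = "site_id"
    frame["sampling_class"] = (frame["visits"] - 1) // 3 + 1
    return frame


def gen_traits(n_species: int, n_traits: int = 3, levels: int = 3, seed=None,
               species_ids=None) -> pd.DataFrame:
    """Categorical trait table: ``n_traits`` columns of uniform draws."""
    rng = _rng(seed)
    if species_ids is None:
        species_ids = _labels("sp", n_species)
    data = {
        f"trait{k + 1}": [f"level{v + 1}" for v in rng.integers(0, levels, n_species)]
        for k in range(n_traits)
    }
    frame = pd.DataFrame(data, index=list(map(str, species_ids)))
    frame.index.name = "species_id"
    return frame


# ---------------------------------------------------------------------------
# regional-census preset


@dataclass
class SyntheticBundle:
    matrix: IncidenceMatrix
    metadata: pd.DataFrame
    taxonomy: TaxonomyTable
    traits: pd.DataFrame


def regional_census_dataset(seed=None, n_species: int = 141, n_sites: int = 189,
                        capacity_logmedian: float = np.log(4.0),
                        capacity_logsd: float = 0.8,
                        length_effect: float = 0.288,
                        longitude_effect: float = 0.30,
                        weight_logsd: float = 1.5) -> SyntheticBundle:
    """Drift-assembled metacommunity at regional karst-census scale.

    Per-cave capacity is lognormal around a median of 4 species with a
    total log-scale SD of ``capacity_logsd`` (0.8 gives mean richness
    ~5.6, max ~30 over 189 caves, hence beta_P ~= 0.96 and a z slope
    near 0.6-0.7).  Part of that log-variance is structured:
    ``length_effect`` loads ln-capacity on standardized ln(cave length)
    (0.288 out of 0.8 puts the log-log richness-length r-squared near
    0.13) and ``longitude_effect`` adds an east-west richness gradient
    so longitude-sorted windows span a richness range, as regional
    censuses do.  Species colonization weights are lognormal with
    log-SD ``weight_logsd``, producing the heavy occupancy skew (one
    near-ubiquitous species, dozens of single-cave endemics) typical of
    cave faunas.
    """
    seed_seq = seed if isinstance(seed, np.random.SeedSequence) else \
        np.random.SeedSequence(seed)
    s_meta, s_cap, s_assemble, s_tax, s_traits = \
        [np.random.default_rng(c) for c in seed_seq.spawn(5)]

    metadata = gen_cave_metadata(n_sites, seed=s_meta)
    z_len = np.log(metadata["length_m"].to_numpy())
    z_len = (z_len - z_len.mean()) / z_len.std()
    z_lon = metadata["longitude"].to_numpy()
    z_lon = (z_lon - z_lon.mean()) / z_lon.std()
    resid_sd = np.sqrt(max(capacity_logsd ** 2 - length_effect ** 2
                           - longitude_effect ** 2, 0.0))
    ln_cap = (capacity_logmedian + length_effect * z_len
              - longitude_effect * z_lon + resid_sd * s_cap.normal(size=n_sites))
    capacities = np.clip(np.round(np.exp(ln_cap)).astype(int), 1, n_species)

    weights = np.exp(weight_logsd * s_cap.normal(size=n_species))
    matrix = gen_drift_assembly(weights, capacities, seed=s_assemble)

    taxonomy = gen_taxonomy(n_species, children_per_rank=(4, 2, 2, 2, 2, 2, 3, 2),
                            seed=s_tax, species_ids=matrix.species_ids)
    traits = gen_traits(n_species, n_traits=3, levels=3, seed=s_traits,
                        species_ids=matrix.species_ids)
    return SyntheticBundle(matrix, metadata, taxonomy, traits)
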