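"""Co-occurrence metrics: checkerboard units, C-score, and NODF.

The C-score measures pairwise segregation.  For species i and j with
occupancies r_i, r_j and S_ij jointly occupied sites, the number of
checkerboard units CU_ij = (r_i - S_ij)(r_j - S_ij) equals the number of
2x2 submatrices of the form {{1,0},{0,1}} or {{0,1},{1,0}} that the pair
forms across sites; the matrix-level C-score is the mean CU over all
unordered species pairs.

NODF (nestedness by overlap and decreasing fill) scores, for every pair
of rows and every pair of columns with unequal marginal totals, the
percentage of the poorer member's occurrences contained in the richer
member; pairs with tied totals contribute zero.  The score is the mean
over all row and column pairs, in [0, 100].
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from cavecom.community_data import IncidenceMatrix
from cavecom.null_models import NullEnsemble


def _values(matrix) -> np.ndarray:
    if isinstance(matrix, IncidenceMatrix):
        return matrix.values
    return np.asarray(matrix, dtype=np.int8)


def checkerboard_units(matrix: IncidenceMatrix, species_a: str, species_b: str) -> int:
    """Number of 2x2 checkerboard submatrices formed by one species pair."""
    ia, ib = matrix.species_index(species_a), matrix.species_index(species_b)
    rows = matrix.values
    shared = int(np.dot(rows[ia], rows[ib]))
    ra, rb = int(rows[ia].sum()), int(rows[ib].sum())
    return (ra - shared) * (rb - shared)


def _cu_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise CU for all species pairs (full symmetric matrix)."""
    values = values.astype(np.int64)
    shared = values @ values.T
    r = values.sum(axis=1)
    return (r[:, None] - shared) * (r[None, :] - shared)


def c_score(matrix) -> float:
    """Mean checkerboard units over all unordered species pairs."""
    values = _values(matrix)
    n = values.shape[0]
    if n < 2:
        raise ValueError("C-score needs at least two species")
    cu = _cu_matrix(values)
    iu = np.triu_indices(n, k=1)
    return float(cu[iu].mean())


def _nodf_axis(values: np.ndarray) -> tuple[float, int]:
    """Sum of paired nestedness over row pairs, and the pair count."""
    values = values.astype(np.int64)
    n = values.shape[0]
    if n < 2:
        return 0.0, 0
    fills = values.sum(axis=1)
    shared = values @ values.T
    fi = fills[:, None]
    fj = fills[None, :]
    smaller = np.minimum(fi, fj)
    with np.errstate(divide="ignore", invalid="ignore"):
        paired = np.where((fi != fj) & (smaller > 0),
                          100.0 * shared / np.where(smaller > 0, smaller, 1), 0.0)
    iu = np.triu_indices(n, k=1)
    return float(paired[iu].sum()), len(iu[0])


def nodf(matrix) -> float:
    """NODF nestedness score in [0, 100].

    Marginal totals, not physical matrix order, decide the richer member
    of each pair, so the score is invariant to row/column permutation.
    """
    values = _values(matrix)
    if values.ndim != 2 or min(values.shape) < 2:
        raise ValueError("NODF needs at least 2 rows and 2 columns")
    if values.sum() == 0:
        raise ValueError("NODF undefined on an empty matrix")
    row_sum, row_pairs = _nodf_axis(values)
    col_sum, col_pairs = _nodf_axis(values.T)
    return (row_sum + col_sum) / (row_pairs + col_pairs)


def pairwise_c_scores(matrix: IncidenceMatrix, ensemble: NullEnsemble) -> pd.DataFrame:
    """Per-pair checkerboard units with SES against a null ensemble.

    Returns one row per unordered species pair with the observed CU, the
    null mean/SD over the ensemble, the standardized effect size
    (NaN where the null variance is zero), and add-one empirical tail
    probabilities.  Positive SES marks segregation (more checkerboards
    than expected), negative SES aggregation.
    """
    if ensemble.species_ids != matrix.species_ids or \
            len(ensemble.site_ids) != matrix.n_sites:
        raise ValueError("ensemble was not built from this matrix")
    n = matrix.n_species
    iu = np.triu_indices(n, k=1)
    values = matrix.values.astype(np.int64)
    obs_shared = (values @ values.T)[iu]
    obs_cu = _cu_matrix(matrix.values)[iu]

    reps = len(ensemble.matrices)
    null_cu = np.empty((reps, len(iu[0])), dtype=np.int64)
    for k, null in enumerate(ensemble.matrices):
        null_cu[k] = _cu_matrix(null)[iu]

    null_mean = null_cu.mean(axis=0)
    null_sd = null_cu.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ses = np.where(null_sd > 0, (obs_cu - null_mean) / null_sd, np.nan)
    p_upper = ((null_cu >= obs_cu).sum(axis=0) + 1) / (reps + 1)
    p_lower = ((null_cu <= obs_cu).sum(axis=0) + 1) / (reps + 1)

    species = np.asarray(matrix.species_ids)
    return pd.DataFrame({
        "species_a": species[iu[0]],
        "species_b": species[iu[1]],
        "shared": obs_shared,
        "cu": obs_cu,
        "null_mean": null_mean,
        "null_sd": null_sd,
        "ses": ses,
        "p_lower": p_lower,
        "p_upper": p_upper,
    })
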