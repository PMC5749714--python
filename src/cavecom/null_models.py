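"""Randomization null models for incidence matrices and SES machinery.

Three ensembles are provided, differing in which observed structure they
preserve:

EE (equiprobable)
    F occurrences placed uniformly at random among distinct cells.
    Preserves only the total fill F.
PP (proportional)
    Occurrences placed without replacement with selection probability
    proportional to the product of observed row and column totals
    (renormalized over unoccupied cells after each draw).  Preserves F
    exactly and the marginals in expectation; mimics passive sampling
    from a pool with unequal colonization weights and site capacities.
FF (fixed-fixed)
    Sequential swap chain: random 2x2 checkerboard submatrices are
    flipped, preserving every row and column total exactly.

EE and PP condition on no empty row or column (whole-matrix rejection
sampling), since an empty row or column changes the species pool / site
set and breaks downstream metrics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from cavecom.community_data import IncidenceMatrix

logger = logging.getLogger(__name__)

#: rejection-sampling cap for the no-empty-row/column constraint
MAX_REJECTION_ATTEMPTS = 10_000


def _as_matrix(matrix) -> IncidenceMatrix:
    if isinstance(matrix, IncidenceMatrix):
        return matrix
    values = np.asarray(matrix, dtype=np.int8)
    return IncidenceMatrix(values,
                           tuple(f"sp{i}" for i in range(values.shape[0])),
                           tuple(f"site{j}" for j in range(values.shape[1])))


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _check_feasible(shape, fill) -> None:
    n_rows, n_cols = shape
    if fill < max(n_rows, n_cols):
        raise ValueError(
            f"fill {fill} too small to avoid empty rows/columns in a "
            f"{n_rows}x{n_cols} matrix"
        )
    if fill > n_rows * n_cols:
        raise ValueError("fill exceeds matrix size")


def _no_empty(values: np.ndarray) -> bool:
    return values.sum(axis=1).all() and values.sum(axis=0).all()


def _place_uniform(shape, fill, rng) -> np.ndarray:
    values = np.zeros(shape[0] * shape[1], dtype=np.int8)
    values[rng.choice(values.size, size=fill, replace=False)] = 1
    return values.reshape(shape)


def _place_proportional(shape, fill, weights, rng) -> np.ndarray:
    # Weighted sampling without replacement via exponential sort
    # (equivalent to sequential draws with renormalized probabilities).
    keys = rng.exponential(size=weights.size) / weights
    chosen = np.argpartition(keys, fill - 1)[:fill]
    values = np.zeros(weights.size, dtype=np.int8)
    values[chosen] = 1
    return values.reshape(shape)


def _rejection_sample(place, shape, fill) -> np.ndarray:
    for _ in range(MAX_REJECTION_ATTEMPTS):
        values = place()
        if _no_empty(values):
            return values
    raise RuntimeError(
        f"could not place fill {fill} in shape {shape} without empty "
        f"rows/columns in {MAX_REJECTION_ATTEMPTS} attempts"
    )


def randomize_EE(matrix, seed=None, require_no_empty: bool = True) -> IncidenceMatrix:
    """Equiprobable randomization: uniform placement of F occurrences.

    With ``require_no_empty`` (default) the matrix is resampled until no
    row or column is empty.  For sparse matrices (mean occupancy of a
    couple of sites per species) that conditional distribution is
    unreachable by rejection — expected empty rows per draw are then in
    the several-and-up range — so callers analysing sparse submatrices
    disable the constraint, which is also how the classical equiprobable
    null is defined.
    """
    matrix = _as_matrix(matrix)
    rng = _rng(seed)
    shape, fill = matrix.values.shape, matrix.fill
    if not require_no_empty:
        return matrix.with_values(_place_uniform(shape, fill, rng))
    _check_feasible(shape, fill)
    values = _rejection_sample(lambda: _place_uniform(shape, fill, rng), shape, fill)
    return matrix.with_values(values)


def randomize_PP(matrix, seed=None, require_no_empty: bool = True) -> IncidenceMatrix:
    """Proportional randomization: placement probability of each cell
    proportional to (row total) x (column total), without replacement
    (renormalized after each draw), optionally resampled until no row or
    column is empty."""
    matrix = _as_matrix(matrix)
    rng = _rng(seed)
    shape, fill = matrix.values.shape, matrix.fill
    weights = np.outer(matrix.row_totals, matrix.col_totals).astype(float).ravel()
    weights = np.maximum(weights, 1e-12)  # guard: zero marginals cannot occur post-validation
    if not require_no_empty:
        return matrix.with_values(_place_proportional(shape, fill, weights, rng))
    _check_feasible(shape, fill)
    values = _rejection_sample(
        lambda: _place_proportional(shape, fill, weights, rng), shape, fill)
    return matrix.with_values(values)


def randomize_FF(matrix, n_swaps=None, seed=None) -> IncidenceMatrix:
    """Fixed-fixed randomization by sequential checkerboard swaps.

    Picks random row pairs and column pairs; whenever they form a 2x2
    checkerboard, flips it.  Row and column totals are conserved
    exactly.  ``n_swaps`` counts successful swaps (default 10 x F, a
    conventional burn-in length for swap chains).  If the matrix has no
    swappable submatrix the input is returned with a warning.
    """
    matrix = _as_matrix(matrix)
    rng = _rng(seed)
    values = matrix.values.copy()
    if n_swaps is None:
        n_swaps = 10 * matrix.fill
    cu = _total_checkerboards(values)
    if cu == 0:
        warnings.warn("matrix has no checkerboard submatrix; returned unchanged")
        return matrix.with_values(values)
    _swap_chain(values, n_swaps, rng)
    return matrix.with_values(values)


def _total_checkerboards(values: np.ndarray) -> int:
    v = values.astype(np.int64)
    shared = v @ v.T
    r = v.sum(axis=1)
    cu = (r[:, None] - shared) * (r[None, :] - shared)
    return int(np.triu(cu, k=1).sum())


def _swap_chain(values: np.ndarray, n_swaps: int, rng: np.random.Generator,
                attempt_cap_factor: int = 1000) -> int:
    """Run ``n_swaps`` successful checkerboard flips in place; returns the
    number actually performed (may be fewer if the attempt cap is hit)."""
    n_rows, n_cols = values.shape
    done = 0
    attempts = 0
    cap = attempt_cap_factor * max(n_swaps, 1)
    batch = max(256, 4 * n_swaps)
    while done < n_swaps and attempts < cap:
        rows = rng.integers(0, n_rows, size=(batch, 2))
        cols = rng.integers(0, n_cols, size=(batch, 2))
        for (i, j), (k, l) in zip(rows, cols):
            attempts += 1
            if i == j or k == l:
                continue
            a, b, c, d = values[i, k], values[i, l], values[j, k], values[j, l]
            if a == d and b == c and a != b:
                values[i, k] = b
                values[i, l] = a
                values[j, k] = a
                values[j, l] = b
                done += 1
                if done >= n_swaps:
                    break
            if attempts >= cap:
                break
    if done < n_swaps:
        warnings.warn(f"swap chain performed only {done}/{n_swaps} swaps "
                      f"within the attempt cap")
    return done


_RANDOMIZERS = {"EE": randomize_EE, "PP": randomize_PP}


@dataclass
class NullEnsemble:
    """A set of randomized matrices from one null model."""

    model: str
    reps: int
    seed: object
    species_ids: tuple[str, ...]
    site_ids: tuple[str, ...]
    matrices: list[np.ndarray] = field(repr=False, default_factory=list)

    def metric_values(self, metric) -> np.ndarray:
        """Apply a metric (callable on a 0/1 ndarray) across the ensemble."""
        return np.array([metric(m) for m in self.matrices], dtype=float)


def build_ensemble(matrix, model: str, reps: int = 200, seed=None,
                   burn_in: int | None = None, thin: int | None = None,
                   require_no_empty: bool = True) -> NullEnsemble:
    """Build a reproducible ensemble of ``reps`` randomized matrices.

    EE/PP draw independent randomizations from per-rep spawned seeds.
    FF runs one swap chain: ``burn_in`` successful swaps (default 10 x F)
    then a matrix saved every ``thin`` swaps (default F).

    Conservation is asserted on every generated matrix: fill for EE/PP,
    all marginals for FF.
    """
    matrix = _as_matrix(matrix)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if model not in ("EE", "PP", "FF"):
        raise ValueError(f"unknown null model {model!r}")
    seed_seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    out: list[np.ndarray] = []
    if model in _RANDOMIZERS:
        randomize = _RANDOMIZERS[model]
        for child in seed_seq.spawn(reps):
            null = randomize(matrix, np.random.default_rng(child),
                             require_no_empty=require_no_empty)
            assert null.fill == matrix.fill, "null model failed to conserve fill"
            out.append(null.values)
    else:
        fill = matrix.fill
        burn_in = 10 * fill if burn_in is None else burn_in
        thin = fill if thin is None else thin
        rng = np.random.default_rng(seed_seq)
        values = matrix.values.copy()
        if _total_checkerboards(values) == 0:
            warnings.warn("matrix has no checkerboard submatrix; FF ensemble "
                          "repeats the observed matrix")
            out = [values.copy() for _ in range(reps)]
        else:
            _swap_chain(values, burn_in, rng)
            row_t, col_t = matrix.row_totals, matrix.col_totals
            for _ in range(reps):
                _swap_chain(values, thin, rng)
                assert (values.sum(axis=1) == row_t).all() and \
                       (values.sum(axis=0) == col_t).all(), \
                       "FF failed to conserve marginals"
                out.append(values.copy())
    return NullEnsemble(model, reps, seed, matrix.species_ids, matrix.site_ids, out)


@dataclass
class SESResult:
    """Observed metric vs a null distribution.

    ses = (observed - null_mean) / null_sd, NaN when the null has zero
    variance; p_lower/p_upper are add-one empirical tail probabilities,
    so the smallest attainable p with n null values is 1/(n+1).
    """

    observed: float
    null_mean: float
    null_sd: float
    ses: float
    p_lower: float
    p_upper: float
    reps: int

    @property
    def significant(self) -> bool:
        """Two-sided 5% call under approximate normality (|SES| > 1.96)."""
        return np.isfinite(self.ses) and abs(self.ses) > 1.96


def ses(observed: float, null_values) -> SESResult:
    """Standardized effect size of an observed metric against null values."""
    null_values = np.asarray(null_values, dtype=float)
    n = null_values.size
    if n < 2:
        raise ValueError("need at least two null values")
    mean = float(null_values.mean())
    sd = float(null_values.std(ddof=1))
    z = (observed - mean) / sd if sd > 0 else float("nan")
    p_upper = (int((null_values >= observed).sum()) + 1) / (n + 1)
    p_lower = (int((null_values <= observed).sum()) + 1) / (n + 1)
    return SESResult(float(observed), mean, sd, z, p_lower, p_upper, n)


def metric_ses(matrix, metric, model: str = "EE", reps: int = 200, seed=None,
               ensemble: NullEnsemble | None = None) -> SESResult:
    """Convenience: observed metric vs a (possibly shared) null ensemble."""
    matrix = _as_matrix(matrix)
    if ensemble is None:
        ensemble = build_ensemble(matrix, model, reps=reps, seed=seed)
    return ses(metric(matrix.values), ensemble.metric_values(metric))
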