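"""Longitude-sorted shifting windows and the spatial eigenvector covariate.

The shifting-window analysis asks how co-occurrence structure varies
across the study region: sites are sorted by longitude, cut into
consecutive non-overlapping windows of equal size, and each window's
sub-metacommunity is scored (C-score and NODF SES against null
ensembles).  EV1, the dominant eigenvector of the inter-site Euclidean
distance matrix, serves as a spatial covariate in the regression models
to absorb broad-scale spatial non-independence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cavecom.community_data import IncidenceMatrix
from cavecom.cooccurrence import c_score, nodf
from cavecom.null_models import build_ensemble, ses
from cavecom.inference import permutation_ols


@dataclass
class WindowAssignment:
    windows: list[list[str]]
    unassigned: list[str]

    @property
    def n_windows(self) -> int:
        return len(self.windows)


def make_windows(metadata: pd.DataFrame, window_size: int = 20,
                 n_windows: int = 9) -> WindowAssignment:
    """Partition sites into consecutive longitude-sorted windows.

    Sites are sorted by longitude ascending (ties broken by latitude,
    then site id, so the assignment is deterministic); the first
    ``n_windows * window_size`` sites are cut into consecutive blocks and
    the surplus at the high-longitude end is left unassigned.
    """
    needed = window_size * n_windows
    if len(metadata) < needed:
        raise ValueError(f"need at least {needed} sites, have {len(metadata)}")
    order = metadata.assign(_site=metadata.index.astype(str)).sort_values(
        ["longitude", "latitude", "_site"], kind="mergesort")
    ids = list(order["_site"])
    windows = [ids[k * window_size:(k + 1) * window_size] for k in range(n_windows)]
    return WindowAssignment(windows, ids[needed:])


def window_metrics(matrix: IncidenceMatrix, windows: WindowAssignment,
                   models=("EE",), reps: int = 200, seed=None,
                   n_perm: int = 999,
                   require_no_empty: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """C-score and NODF SES per window, plus SES-vs-richness regressions.

    For each window, the matrix is restricted to the window's sites
    (species rows emptied by the restriction are dropped), ensembles of
    ``reps`` randomizations are built per requested null model, and the
    SES of both metrics recorded.  Windows whose submatrix retains fewer
    than 2 species are flagged (NaN metrics).  Window submatrices are
    sparse (many species occupy a single site within a window), so the
    null ensembles are unconditional by default — conditioning on no
    empty rows is unattainable there and the classical equiprobable /
    proportional nulls do not condition.  The second frame holds,
    per (metric, model), the OLS slope of SES on pooled window richness
    with a permutation p-value.
    """
    seed_seq = np.random.SeedSequence(seed)
    window_seeds = seed_seq.spawn(windows.n_windows)
    rows = []
    for w, (site_ids, child) in enumerate(zip(windows.windows, window_seeds), start=1):
        sub = matrix.subset_sites(site_ids, drop_empty_species=True)
        row = {"window_index": w, "n_sites": len(site_ids),
               "pooled_richness": sub.n_species}
        if sub.n_species < 2:
            for model in models:
                row[f"cscore_ses_{model}"] = np.nan
                row[f"nodf_ses_{model}"] = np.nan
            row["flagged"] = True
        else:
            model_seeds = child.spawn(len(models))
            for model, mseed in zip(models, model_seeds):
                ens = build_ensemble(sub, model, reps=reps, seed=mseed,
                                     require_no_empty=require_no_empty)
                row[f"cscore_ses_{model}"] = ses(
                    c_score(sub.values), ens.metric_values(c_score)).ses
                row[f"nodf_ses_{model}"] = ses(
                    nodf(sub.values), ens.metric_values(nodf)).ses
            row["flagged"] = False
        rows.append(row)
    table = pd.DataFrame(rows)

    reg_seeds = np.random.SeedSequence(seed, spawn_key=(1,)).spawn(2 * len(models))
    reg_rows = []
    usable = table[~table["flagged"]]
    for k, (metric, model) in enumerate(
            [(m, mod) for m in ("cscore", "nodf") for mod in models]):
        col = f"{metric}_ses_{model}"
        y = usable[col].to_numpy()
        x = usable["pooled_richness"].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.sum() >= 3:
            slope, r2, p = permutation_ols(x[ok], y[ok], n_perm=n_perm,
                                           seed=np.random.default_rng(reg_seeds[k]))
        else:
            slope, r2, p = np.nan, np.nan, np.nan
        reg_rows.append({"metric": metric, "model": model, "slope": slope,
                         "r2": r2, "p_perm": p, "n_windows": int(ok.sum())})
    return table, pd.DataFrame(reg_rows)


def ev1(metadata: pd.DataFrame, method: str = "pcoa") -> pd.Series:
    """First spatial eigenvector of the inter-site distance matrix.

    ``method='pcoa'`` (default) double-centres the squared Euclidean
    distances and takes the first principal coordinate scaled by the
    square root of its eigenvalue; ``method='raw'`` takes the dominant
    eigenvector of the raw distance matrix, centred.  Either way the
    orientation is fixed so the scores correlate positively with
    longitude, making the sign deterministic.
    """
    coords = metadata[["longitude", "latitude"]].to_numpy(dtype=float)
    if coords.shape[0] < 3:
        raise ValueError("need at least 3 sites with coordinates")
    if np.allclose(coords, coords[0]):
        raise ValueError("all coordinates identical: no spatial variance")
    diff = coords[:, None, :] - coords[None, :, :]
    d2 = (diff ** 2).sum(axis=-1)
    if method == "pcoa":
        n = d2.shape[0]
        centering = np.eye(n) - np.ones((n, n)) / n
        gram = -0.5 * centering @ d2 @ centering
        eigval, eigvec = np.linalg.eigh(gram)
        scores = eigvec[:, -1] * np.sqrt(max(eigval[-1], 0.0))
    elif method == "raw":
        eigval, eigvec = np.linalg.eigh(np.sqrt(d2))
        # dominant by absolute eigenvalue
        k = int(np.argmax(np.abs(eigval)))
        scores = eigvec[:, k]
        scores = scores - scores.mean()
    else:
        raise ValueError(f"unknown method {method!r}")
    lon = coords[:, 0]
    corr = np.corrcoef(scores, lon)[0, 1] if np.std(scores) > 0 else 0.0
    if corr < 0:
        scores = -scores
    return pd.Series(scores, index=metadata.index.astype(str), name="ev1")
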