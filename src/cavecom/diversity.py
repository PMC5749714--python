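"""Richness summaries, proportional beta-diversity, endemism, allometry.

Proportional turnover is beta_P = 1 - alpha/gamma where alpha is the mean
per-site richness and gamma the pool richness; it is the proportion of the
pool absent from a site of average richness, ranging from 0 (every site
holds the whole pool) to 1 (perfect local uniqueness).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from cavecom.community_data import IncidenceMatrix


@dataclass
class DiversitySummary:
    alpha_mean: float
    alpha_median: float
    alpha_min: int
    alpha_max: int
    gamma: int
    beta_p_mean: float
    beta_p_se: float
    z_slope: float


def site_richness(matrix: IncidenceMatrix) -> pd.Series:
    """Per-site species counts c_j, indexed by site id."""
    if matrix.n_species == 0 or matrix.n_sites == 0:
        raise ValueError("empty matrix")
    return pd.Series(matrix.col_totals, index=list(matrix.site_ids), name="richness")


def richness_summary(matrix: IncidenceMatrix) -> dict:
    r = site_richness(matrix)
    return {"mean": float(r.mean()), "median": float(r.median()),
            "min": int(r.min()), "max": int(r.max())}


def beta_p(matrix: IncidenceMatrix) -> tuple[float, float]:
    """Mean proportional turnover over sites and its standard error.

    Per-site beta_j = 1 - c_j/gamma; the mean equals 1 - alpha/gamma with
    alpha the mean site richness, and the standard error is that of the
    per-site beta values.
    """
    if matrix.n_species == 0 or matrix.n_sites == 0:
        raise ValueError("empty matrix")
    gamma = matrix.n_species
    betas = 1.0 - matrix.col_totals / gamma
    se = float(betas.std(ddof=1) / np.sqrt(betas.size)) if betas.size > 1 else 0.0
    return float(betas.mean()), se


def occupancy(matrix: IncidenceMatrix) -> pd.Series:
    """Per-species site counts r_i, indexed by species id."""
    return pd.Series(matrix.row_totals, index=list(matrix.species_ids),
                     name="occupancy")


def count_single_site_endemics(matrix: IncidenceMatrix) -> int:
    """Species restricted to exactly one site."""
    return int((matrix.row_totals == 1).sum())


def count_species_above_fraction(matrix: IncidenceMatrix, fraction: float) -> int:
    """Species occupying strictly more than ``fraction`` of the sites."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    return int((matrix.row_totals > fraction * matrix.n_sites).sum())


def allometric_z(gamma: float, alpha: float, n_sites: int) -> float:
    """Exponent of the regional-local richness scaling gamma = alpha * N^z.

    z = ln(gamma/alpha) / ln(N); zero when every site holds the whole
    pool, larger when local communities are depauperate relative to it.
    """
    if alpha < 1 or gamma < alpha:
        raise ValueError("need gamma >= alpha >= 1")
    if n_sites < 2:
        raise ValueError("need at least 2 sites")
    return float(np.log(gamma / alpha) / np.log(n_sites))


@dataclass
class PowerLawFit:
    exponent: float
    intercept: float
    r2: float
    p_perm: float
    n_used: int
    n_perm: int


def power_law_fit(response, predictor, n_perm: int = 999, seed=None) -> PowerLawFit:
    """OLS power-law fit of richness against a positive covariate.

    Fits ln(response) = a + z * ln(predictor); significance is assessed
    by permuting the response ``n_perm`` times and counting fits with
    r-squared at least the observed one, with the add-one correction
    (b+1)/(n_perm+1) so p is never zero.  Sites with missing predictor
    are excluded; nonpositive predictors are an error (the log is the
    model, not a transform of convenience).
    """
    response = np.asarray(response, dtype=float)
    predictor = np.asarray(predictor, dtype=float)
    keep = ~np.isnan(predictor) & ~np.isnan(response)
    response, predictor = response[keep], predictor[keep]
    if (predictor <= 0).any():
        raise ValueError("predictor must be > 0 at included sites")
    if (response <= 0).any():
        raise ValueError("response must be > 0 (log-log fit)")
    if response.size < 3:
        raise ValueError("need at least 3 usable sites")
    y = np.log(response)
    x = sm.add_constant(np.log(predictor))
    fit = sm.OLS(y, x).fit()
    r2_obs = float(fit.rsquared)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        r2_null = sm.OLS(rng.permutation(y), x).fit().rsquared
        if r2_null >= r2_obs:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return PowerLawFit(float(fit.params[1]), float(fit.params[0]), r2_obs, p,
                       int(response.size), n_perm)


def diversity_summary(matrix: IncidenceMatrix) -> DiversitySummary:
    """alpha/gamma/beta_P/z in one pass (mean alpha enters beta_P and z;
    the median is reported separately)."""
    summary = richness_summary(matrix)
    mean_bp, se_bp = beta_p(matrix)
    return DiversitySummary(
        alpha_mean=summary["mean"],
        alpha_median=summary["median"],
        alpha_min=summary["min"],
        alpha_max=summary["max"],
        gamma=matrix.n_species,
        beta_p_mean=mean_bp,
        beta_p_se=se_bp,
        z_slope=allometric_z(matrix.n_species, summary["mean"], matrix.n_sites),
    )
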