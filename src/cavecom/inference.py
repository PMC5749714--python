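"""Linear-model inference: partial eta-squared GLMs, pair screening,
and the trait-identity ANOVA on pairwise co-occurrence SES values.

The effect-size currency is partial eta-squared,
SS_effect / (SS_effect + SS_residual), computed by term deletion from a
main-effects (no interaction) least-squares fit — each term's sum of
squares is its increment over the model with that term removed, i.e. the
Type III sum of squares for a main-effects design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class GLMTerm:
    name: str
    ss: float
    df: int
    partial_eta2: float
    sign: str  # '+', '-' or '' for multi-df terms
    f_value: float
    p_value: float

    @property
    def stars(self) -> str:
        if self.p_value < 0.001:
            return "***"
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


@dataclass
class GLMResult:
    response: str
    terms: list[GLMTerm]
    ss_residual: float
    df_residual: int
    r2: float
    nobs: int
    dropped: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"term": t.name, "ss": t.ss, "df": t.df,
              "partial_eta2": t.partial_eta2, "sign": t.sign,
              "F": t.f_value, "p": t.p_value, "stars": t.stars}
             for t in self.terms]
        )

    def __getitem__(self, name: str) -> GLMTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def _term_columns(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """One design block per term; categorical columns expand to dummies."""
    blocks = {}
    for name in table.columns:
        col = table[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            blocks[name] = dummies
        else:
            blocks[name] = col.astype(float).to_frame(name)
    return blocks


def glm_partial_eta2(response: pd.Series, predictors: pd.DataFrame,
                     covariates: pd.DataFrame | None = None,
                     response_name: str | None = None) -> GLMResult:
    """Main-effects least-squares fit with per-term partial eta-squared.

    Each column of ``predictors`` / ``covariates`` is one model term
    (categorical columns become one multi-df term).  Per term: the
    partial SS by deletion, partial eta-squared, an F test, and — for
    single-df terms — the coefficient sign.  Rows with any missing value
    are dropped listwise before fitting.
    """
    frames = [predictors] if covariates is None else [predictors, covariates]
    design_source = pd.concat(frames, axis=1)
    if design_source.columns.duplicated().any():
        raise ValueError("duplicate term names across predictors/covariates")
    y = pd.Series(np.asarray(response, dtype=float),
                  index=design_source.index, name=response_name or
                  (response.name if hasattr(response, "name") else "response"))
    data = pd.concat([y, design_source], axis=1).dropna()
    blocks = _term_columns(data[design_source.columns])
    X_full = pd.concat(blocks.values(), axis=1)
    n, p_full = X_full.shape
    if n < p_full + 3:
        raise ValueError("too few observations for the model size")
    X_full_c = sm.add_constant(X_full.to_numpy(dtype=float))
    if np.linalg.matrix_rank(X_full_c) < X_full_c.shape[1]:
        raise ValueError(
            f"rank-deficient design; check collinearity among terms "
            f"{list(blocks)}"
        )
    yv = data[y.name].to_numpy(dtype=float)
    fit_full = sm.OLS(yv, X_full_c).fit()
    sse_full = float(fit_full.ssr)
    df_resid = int(fit_full.df_resid)

    terms = []
    for name, block in blocks.items():
        others = [b for other, b in blocks.items() if other != name]
        if others:
            X_red = sm.add_constant(pd.concat(others, axis=1).to_numpy(dtype=float))
        else:
            X_red = np.ones((n, 1))
        sse_red = float(sm.OLS(yv, X_red).fit().ssr)
        ss_term = max(sse_red - sse_full, 0.0)
        df_term = block.shape[1]
        eta2 = ss_term / (ss_term + sse_full) if (ss_term + sse_full) > 0 else 0.0
        if df_resid > 0 and sse_full > 0:
            f_val = (ss_term / df_term) / (sse_full / df_resid)
            p_val = float(stats.f.sf(f_val, df_term, df_resid))
        else:
            f_val, p_val = np.inf, 0.0
        sign = ""
        if df_term == 1:
            coef = fit_full.params[1 + list(X_full.columns).index(block.columns[0])]
            sign = "+" if coef > 0 else ("-" if coef < 0 else "")
        terms.append(GLMTerm(name, ss_term, df_term, eta2, sign, f_val, p_val))
    return GLMResult(y.name, terms, sse_full, df_resid,
                     float(fit_full.rsquared), n)


def permutation_ols(x, y, n_perm: int = 999, seed=None) -> tuple[float, float, float]:
    """Simple OLS of y on x with a permutation p for the fit.

    Returns (slope, r2, p) where p = (#{permuted r2 >= observed} + 1) /
    (n_perm + 1) under random reshuffles of y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    r2_obs = float(fit.rsquared)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if sm.OLS(rng.permutation(y), X).fit().rsquared >= r2_obs:
            exceed += 1
    return float(fit.params[1]), r2_obs, (exceed + 1) / (n_perm + 1)


def screen_significant_pairs(pairs: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Keep species pairs with a significant co-occurrence deviation.

    Pairs with p_upper < alpha are tagged ``'segregated'`` (more
    checkerboards than the null), pairs with p_lower < alpha
    ``'aggregated'``.  Most pairs in real matrices do not interact and
    carry uninformative SES values; restricting the trait ANOVA to the
    screened pairs follows the established pre-screening approach.
    """
    segregated = pairs["p_upper"] < alpha
    aggregated = pairs["p_lower"] < alpha
    kept = pairs[segregated | aggregated].copy()
    direction = np.where(kept["p_upper"] < alpha, "segregated", "aggregated")
    both = (kept["p_upper"] < alpha) & (kept["p_lower"] < alpha)
    if both.any():  # can only happen with heavily tied null distributions
        warnings.warn(f"{int(both.sum())} pairs significant in both tails")
    kept["direction"] = direction
    return kept


def trait_identity_anova(pairs: pd.DataFrame, traits: pd.DataFrame,
                         response: str = "ses") -> GLMResult:
    """ANOVA of pair SES on trait-identity codes.

    For every categorical trait, a pair is coded 1 when both species
    share the trait level and 0 otherwise; a main-effects model of the
    pair SES on these codes gives each trait's partial eta-squared.
    Traits whose code is constant across the screened pairs carry no
    information and are dropped with a warning.
    """
    missing = (set(pairs["species_a"]) | set(pairs["species_b"])) - \
        set(traits.index.astype(str))
    if missing:
        raise KeyError(f"species without trait values: {sorted(missing)}")
    codes = {}
    dropped = []
    ta = traits.loc[pairs["species_a"].astype(str)].reset_index(drop=True)
    tb = traits.loc[pairs["species_b"].astype(str)].reset_index(drop=True)
    for trait in traits.columns:
        code = (ta[trait].to_numpy() == tb[trait].to_numpy()).astype(float)
        if np.all(code == code[0]):
            dropped.append(trait)
            continue
        codes[trait] = code
    if not codes:
        raise ValueError("all trait-identity codes are constant across pairs")
    if dropped:
        warnings.warn(f"constant trait codes dropped: {dropped}")
    design = pd.DataFrame(codes, index=pairs.index)
    y = pd.Series(pairs[response].to_numpy(dtype=float), index=pairs.index,
                  name=response)
    result = glm_partial_eta2(y, design)
    result.dropped = dropped
    return result
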