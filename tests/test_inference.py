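import numpy as np
import pandas as pd
import pytest

from cavecom.diversity import power_law_fit
from cavecom.inference import (
    glm_partial_eta2,
    permutation_ols,
    screen_significant_pairs,
    trait_identity_anova,
)


class TestGlmPartialEta2:
    def test_single_predictor_eta2_equals_r2(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=120)
        y = 0.6 * x + rng.normal(size=120)
        result = glm_partial_eta2(pd.Series(y, name="y"),
                                  pd.DataFrame({"x": x}))
        assert result["x"].partial_eta2 == pytest.approx(result.r2)
        assert result["x"].sign == "+"

    def test_constant_response_all_zero(self):
        rng = np.random.default_rng(1)
        result = glm_partial_eta2(
            pd.Series(np.full(50, 3.0), name="y"),
            pd.DataFrame({"x": rng.normal(size=50)}))
        assert result["x"].partial_eta2 == pytest.approx(0.0, abs=1e-12)

    def test_recovers_planted_effect_size(self):
        """A cave-length effect planted to explain ~7% of partial variance
        at n=189 is recovered near its nominal size."""
        rng = np.random.default_rng(2)
        n = 189
        length = rng.normal(size=n)
        altitude = rng.normal(size=n)
        ev = rng.normal(size=n)
        target_eta2 = 0.07
        beta = np.sqrt(target_eta2 / (1 - target_eta2))
        etas = []
        for _ in range(20):
            y = beta * length + rng.normal(size=n)
            result = glm_partial_eta2(
                pd.Series(y, name="richness"),
                pd.DataFrame({"length": length, "altitude": altitude}),
                covariates=pd.DataFrame({"ev1": ev}))
            etas.append(result["length"].partial_eta2)
        assert np.mean(etas) == pytest.approx(target_eta2, abs=0.025)

    def test_affine_response_rescaling_invariant(self):
        rng = np.random.default_rng(3)
        x1 = rng.normal(size=80)
        x2 = rng.normal(size=80)
        y = x1 - 0.5 * x2 + rng.normal(size=80)
        frame = pd.DataFrame({"x1": x1, "x2": x2})
        r1 = glm_partial_eta2(pd.Series(y, name="y"), frame)
        r2 = glm_partial_eta2(pd.Series(5 * y - 11, name="y"), frame)
        for t1, t2 in zip(r1.terms, r2.terms):
            assert t1.partial_eta2 == pytest.approx(t2.partial_eta2)
            assert t1.p_value == pytest.approx(t2.p_value)

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=40)
        with pytest.raises(ValueError, match="rank-deficient"):
            glm_partial_eta2(pd.Series(rng.normal(size=40), name="y"),
                             pd.DataFrame({"x": x, "x2": 2 * x}))

    def test_categorical_term_multi_df_no_sign(self):
        rng = np.random.default_rng(5)
        group = rng.choice(["a", "b", "c"], size=90)
        y = (group == "b") * 1.0 + rng.normal(size=90)
        result = glm_partial_eta2(pd.Series(y, name="y"),
                                  pd.DataFrame({"group": group}))
        assert result["group"].df == 2
        assert result["group"].sign == ""

    def test_agrees_with_permutation_regression(self):
        """Single-predictor F-test and permutation r2 test agree in their
        5%-level rejection decision on most synthetic datasets."""
        rng = np.random.default_rng(6)
        agree = 0
        trials = 40
        for _ in range(trials):
            n = 50
            x = np.exp(rng.normal(size=n))
            y = np.exp(0.15 * np.log(x) + rng.normal(0, 0.5, size=n))
            fit = power_law_fit(y, x, n_perm=399, seed=rng.integers(2**31))
            glm = glm_partial_eta2(
                pd.Series(np.log(y), name="ln_y"),
                pd.DataFrame({"ln_x": np.log(x)}))
            if (fit.p_perm < 0.05) == (glm["ln_x"].p_value < 0.05):
                agree += 1
        assert agree >= 0.95 * trials


class TestPermutationOls:
    def test_strong_slope_significant(self):
        rng = np.random.default_rng(7)
        x = np.arange(30, dtype=float)
        y = 0.5 * x + rng.normal(size=30)
        slope, r2, p = permutation_ols(x, y, n_perm=199, seed=8)
        assert slope == pytest.approx(0.5, abs=0.15)
        assert p <= 0.01


def _pairs_frame(p_lower, p_upper, ses=None):
    n = len(p_lower)
    return pd.DataFrame({
        "species_a": [f"a{i}" for i in range(n)],
        "species_b": [f"b{i}" for i in range(n)],
        "ses": ses if ses is not None else np.zeros(n),
        "p_lower": p_lower,
        "p_upper": p_upper,
    })


class TestScreenSignificantPairs:
    def test_directions_tagged(self):
        pairs = _pairs_frame([0.5, 0.01, 0.9], [0.004, 0.9, 0.5])
        kept = screen_significant_pairs(pairs)
        assert len(kept) == 2
        assert kept.iloc[0]["direction"] == "segregated"
        assert kept.iloc[1]["direction"] == "aggregated"

    def test_nonsignificant_dropped(self):
        pairs = _pairs_frame([0.2, 0.6], [0.3, 0.051])
        assert screen_significant_pairs(pairs).empty


class TestTraitIdentityAnova:
    def test_constant_codes_rejected(self):
        pairs = _pairs_frame([0.01] * 4, [0.9] * 4,
                             ses=[-2.0, -2.5, -1.9, -2.2])
        traits = pd.DataFrame({"habit": ["x"] * 8},
                              index=[f"a{i}" for i in range(4)] +
                                    [f"b{i}" for i in range(4)])
        with pytest.raises(ValueError, match="constant"):
            trait_identity_anova(pairs, traits)

    def test_planted_trait_effect_recovered(self):
        """Pairs sharing the focal trait were planted with higher
        segregation SES; that trait should dominate the ANOVA with a
        positive coefficient."""
        rng = np.random.default_rng(9)
        n = 120
        species = [f"sp{i}" for i in range(2 * n)]
        focal = rng.choice(["m", "n"], size=2 * n)
        noise_trait = rng.choice(["u", "v", "w"], size=2 * n)
        traits = pd.DataFrame({"focal": focal, "other": noise_trait},
                              index=species)
        a = species[:n]
        b = species[n:]
        same = (traits.loc[a, "focal"].to_numpy() ==
                traits.loc[b, "focal"].to_numpy())
        ses_vals = 1.5 * same + rng.normal(size=n)
        pairs = pd.DataFrame({"species_a": a, "species_b": b, "ses": ses_vals,
                              "p_lower": 0.01, "p_upper": 0.99})
        result = trait_identity_anova(pairs, traits)
        assert result["focal"].partial_eta2 > result["other"].partial_eta2
        assert result["focal"].sign == "+"
        assert result["focal"].p_value < 0.001

    def test_random_traits_uniform_pvalues(self):
        """With traits assigned at random the trait ANOVA p-values are
        uniform: ~5% fall below 0.05 across seeded replicates."""
        rng = np.random.default_rng(10)
        hits = 0
        trials = 60
        for _ in range(trials):
            n = 60
            species = [f"sp{i}" for i in range(2 * n)]
            traits = pd.DataFrame(
                {"t": rng.choice(["x", "y"], size=2 * n)}, index=species)
            pairs = pd.DataFrame({
                "species_a": species[:n], "species_b": species[n:],
                "ses": rng.normal(size=n), "p_lower": 0.01, "p_upper": 0.99,
            })
            result = trait_identity_anova(pairs, traits)
            if result["t"].p_value < 0.05:
                hits += 1
        assert hits / trials < 0.15
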