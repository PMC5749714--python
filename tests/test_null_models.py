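import itertools

import numpy as np
import pytest

from cavecom.community_data import IncidenceMatrix
from cavecom.cooccurrence import c_score
from cavecom.null_models import (
    build_ensemble,
    metric_ses,
    randomize_EE,
    randomize_FF,
    randomize_PP,
    ses,
)
from cavecom.synthetic import gen_drift_assembly, gen_random_matrix


def _matrix(values):
    values = np.asarray(values)
    return IncidenceMatrix(values,
                           [f"sp{i}" for i in range(values.shape[0])],
                           [f"s{j}" for j in range(values.shape[1])])


class TestRandomizeEE:
    def test_full_matrix_unchanged(self):
        m = _matrix(np.ones((3, 4), dtype=int))
        assert (randomize_EE(m, seed=0).values == 1).all()

    def test_fill_conserved(self):
        m = gen_random_matrix(8, 10, 30, seed=1)
        null = randomize_EE(m, seed=2)
        assert null.fill == m.fill
        assert null.values.shape == m.values.shape

    def test_infeasible_fill_errors(self):
        m = _matrix(np.eye(4, dtype=int))
        # fill 4 == max(4,4) is feasible; drop below by hand
        tiny = IncidenceMatrix(np.array([[1, 0, 0], [0, 1, 0]]),
                               ("a", "b"), ("s1", "s2", "s3"))
        with pytest.raises(ValueError):
            randomize_EE(tiny, seed=3)

    def test_cell_frequencies_uniform(self):
        # 10x10, F=30: each cell occupied in ~30% of draws (conditioning
        # on no-empty preserves the symmetric per-cell expectation)
        m = gen_random_matrix(10, 10, 30, seed=4)
        counts = np.zeros((10, 10))
        reps = 2000
        rng = np.random.default_rng(5)
        for _ in range(reps):
            counts += randomize_EE(m, seed=rng).values
        freq = counts / reps
        sd = np.sqrt(0.3 * 0.7 / reps)
        outside = int((np.abs(freq - 0.3) > 3 * sd).sum())
        assert outside <= 3  # ~0.27 cells expected outside 3 SDs


class TestRandomizePP:
    def test_fill_conserved(self):
        m = gen_random_matrix(8, 10, 30, seed=6)
        assert randomize_PP(m, seed=7).fill == m.fill

    def test_null_marginals_track_observed(self):
        # skewed marginals: mean null row totals correlate with observed
        rng = np.random.default_rng(8)
        weights = np.exp(1.2 * rng.normal(size=15))
        caps = np.clip(rng.poisson(5, size=20), 1, 15)
        m = gen_drift_assembly(weights, caps, seed=9)
        total = np.zeros(m.n_species)
        reps = 500
        for _ in range(reps):
            total += randomize_PP(m, seed=rng).row_totals
        from scipy.stats import spearmanr

        rho = spearmanr(total / reps, m.row_totals).statistic
        assert rho > 0.9


class TestRandomizeFF:
    def test_2x2_checkerboard_flips(self):
        m = _matrix([[1, 0], [0, 1]])
        flipped = randomize_FF(m, n_swaps=1, seed=10)
        assert (flipped.values == np.array([[0, 1], [1, 0]])).all()

    def test_marginals_conserved(self):
        m = gen_random_matrix(10, 12, 40, seed=11)
        null = randomize_FF(m, seed=12)
        assert (null.row_totals == m.row_totals).all()
        assert (null.col_totals == m.col_totals).all()

    def test_no_swappable_submatrix_warns(self):
        m = _matrix(np.ones((2, 2), dtype=int))
        with pytest.warns(UserWarning, match="no checkerboard"):
            null = randomize_FF(m, n_swaps=5, seed=13)
        assert (null.values == m.values).all()

    def test_reaches_every_configuration_with_same_marginals(self):
        # 3x3 permutation matrix: the swap chain must visit all 6
        # configurations with unit marginals
        start = np.eye(3, dtype=int)
        expected = set()
        for perm in itertools.permutations(range(3)):
            values = np.zeros((3, 3), dtype=int)
            values[range(3), perm] = 1
            expected.add(values.tobytes())
        seen = set()
        values = start.copy()
        rng = np.random.default_rng(14)
        m = _matrix(start)
        for _ in range(300):
            m = randomize_FF(m, n_swaps=1, seed=rng)
            seen.add(m.values.astype(int).tobytes())
        assert seen == expected


class TestBuildEnsemble:
    def test_deterministic_given_seed(self):
        m = gen_random_matrix(8, 10, 30, seed=15)
        e1 = build_ensemble(m, "PP", reps=20, seed=16)
        e2 = build_ensemble(m, "PP", reps=20, seed=16)
        assert all((a == b).all() for a, b in zip(e1.matrices, e2.matrices))

    def test_zero_reps_rejected(self):
        m = gen_random_matrix(5, 5, 12, seed=17)
        with pytest.raises(ValueError):
            build_ensemble(m, "EE", reps=0, seed=18)

    @pytest.mark.parametrize("model", ["EE", "PP", "FF"])
    def test_conservation_across_models(self, model):
        m = gen_random_matrix(9, 11, 35, seed=19)
        ens = build_ensemble(m, model, reps=15, seed=20)
        for null in ens.matrices:
            assert null.sum() == m.fill
            if model == "FF":
                assert (null.sum(axis=1) == m.row_totals).all()
                assert (null.sum(axis=0) == m.col_totals).all()


class TestSes:
    def test_zero_when_observed_at_mean(self):
        null = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert ses(3.0, null).ses == 0.0

    def test_two_sd_above(self):
        null = np.random.default_rng(21).normal(10, 2, size=5000)
        result = ses(null.mean() + 2 * null.std(ddof=1), null)
        assert result.ses == pytest.approx(2.0)

    def test_add_one_rule(self):
        null = np.arange(200, dtype=float)
        result = ses(1000.0, null)
        assert result.p_upper == pytest.approx(1 / 201)
        assert result.p_lower == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        result = ses(5.0, np.full(10, 3.0))
        assert np.isnan(result.ses)
        assert 0 < result.p_upper <= 1


def test_ee_vs_pp_discrimination_on_drift_matrices():
    """On passive-sampling matrices with skewed marginals the equiprobable
    null overstates segregation relative to the proportional null."""
    rng = np.random.default_rng(22)
    for trial in range(3):
        weights = np.exp(1.5 * rng.normal(size=40))
        caps = np.clip(np.round(np.exp(np.log(5) + 0.7 * rng.normal(size=60))).astype(int), 1, 40)
        m = gen_drift_assembly(weights, caps, seed=rng)
        z_ee = metric_ses(m, c_score, "EE", reps=200, seed=rng.integers(2**31)).ses
        z_pp = metric_ses(m, c_score, "PP", reps=200, seed=rng.integers(2**31)).ses
        assert abs(z_ee) > abs(z_pp)
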