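"""Split-data RSMs, CDI, Kendall tau-a model correlation, group inference."""


import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from facemvpa import rsa

from tests.conftest import make_noise_patterns


def brute_force_sdrsm(betas, half_a, half_b):
    """Two-loop Pearson correlation oracle for a single run split."""
    n_cond = betas.shape[1]
    mean_a = betas[half_a].mean(axis=0)
    mean_b = betas[half_b].mean(axis=0)
    out = np.empty((n_cond, n_cond))
    for i in range(n_cond):
        for j in range(n_cond):
            out[i, j] = np.corrcoef(mean_a[i], mean_b[j])[0, 1]
    return out


def brute_force_tau_a(x, y):
    """Exhaustive concordant/discordant pair enumeration."""
    n = len(x)
    num = 0
    for i in range(n):
        for j in range(i + 1, n):
            num += np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
    return num / (n * (n - 1) / 2)


def brute_force_bh(p_values, alpha):
    """BH step-up oracle: largest k with p_(k) <= k*alpha/m."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * alpha / m:
            k_star = k
    flags = np.zeros(m, dtype=bool)
    flags[order[:k_star]] = True
    return flags


class TestMeanSubtract:
    def test_condition_mean_is_zero(self):
        p = make_noise_patterns(4, 5, 30, seed=1)
        out = rsa.mean_subtract(p)
        assert np.abs(out.betas.mean(axis=1)).max() < 1e-12

    def test_identical_conditions_become_zero(self):
        p = make_noise_patterns(2, 2, 10, seed=2)
        p.betas[:, 1, :] = p.betas[:, 0, :]
        out = rsa.mean_subtract(p)
        assert np.allclose(out.betas, 0.0)

    def test_three_condition_arithmetic(self):
        p = make_noise_patterns(1, 3, 1, seed=3)
        p.betas[0, :, 0] = [1.0, 2.0, 3.0]
        out = rsa.mean_subtract(p)
        assert np.allclose(out.betas[0, :, 0], [-1.0, 0.0, 1.0])

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError):
            rsa.mean_subtract(make_noise_patterns(2, 1, 5, seed=4))


class TestSplitRsm:
    def test_single_split_matches_brute_force_oracle(self):
        p = make_noise_patterns(8, 4, 25, seed=5)
        splits = rsa.half_partitions(8, 1, seed=6)
        rsm = rsa.split_rsm(p, splits=splits)
        oracle = brute_force_sdrsm(p.betas, *splits[0])
        assert np.allclose(rsm.matrix, oracle, atol=1e-12)

    def test_exhaustive_permutations_match_enumeration_oracle(self):
        p = make_noise_patterns(4, 3, 12, seed=7)
        all_splits = rsa.half_partitions(4, None, exhaustive=True)
        assert len(all_splits) == 3  # C(3,1) unordered balanced partitions
        rsm = rsa.split_rsm(p, n_permutations=999, seed=1)  # clips to all 3
        oracle = np.mean([brute_force_sdrsm(p.betas, a, b) for a, b in all_splits],
                         axis=0)
        assert np.allclose(rsm.matrix, oracle, atol=1e-12)

    def test_noiseless_identical_halves_give_unit_diagonal(self):
        p = make_noise_patterns(4, 4, 20, seed=8)
        p.betas[:] = p.betas[0]  # identical patterns in every run
        rsm = rsa.split_rsm(p, n_permutations=3, seed=9)
        assert np.allclose(np.diag(rsm.matrix), 1.0)

    def test_symmetrize_averages_transpose_pairs(self):
        p = make_noise_patterns(6, 4, 15, seed=10)
        plain = rsa.split_rsm(p, n_permutations=5, seed=11)
        sym = rsa.split_rsm(p, n_permutations=5, seed=11, symmetrize=True)
        assert np.allclose(sym.matrix, (plain.matrix + plain.matrix.T) / 2)
        assert np.allclose(sym.matrix, sym.matrix.T)

    def test_odd_run_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            rsa.split_rsm(make_noise_patterns(5, 3, 10, seed=12), n_permutations=2)

    def test_zero_variance_pattern_propagates_missing(self):
        p = make_noise_patterns(4, 3, 10, seed=13)
        p.betas[:, 0, :] = 1.0  # constant pattern in every run
        with pytest.warns(UserWarning, match="zero-variance"):
            rsm = rsa.split_rsm(p, n_permutations=2, seed=14)
        assert np.isnan(rsm.matrix[0]).all()
        assert np.isfinite(rsm.matrix[1:, 1:]).all()


class TestCdi:
    @pytest.mark.parametrize(
        "matrix,expected",
        [
            (np.eye(3), 1.0),
            (np.full((4, 4), 0.37), 0.0),
            (np.array([[0.8, 0.2], [0.4, 0.6]]), 0.4),
        ],
    )
    def test_known_values(self, matrix, expected):
        assert rsa.cdi(matrix) == pytest.approx(expected)

    def test_invariant_under_simultaneous_permutation(self):
        rng = np.random.default_rng(15)
        m = rng.uniform(-1, 1, (5, 5))
        perm = rng.permutation(5)
        assert rsa.cdi(m[np.ix_(perm, perm)]) == pytest.approx(rsa.cdi(m))

    def test_missing_entries_excluded_with_warning(self):
        m = np.eye(3)
        m[0, 1] = np.nan
        with pytest.warns(UserWarning, match="missing"):
            assert rsa.cdi(m) == pytest.approx(1.0)


class TestModelCorrelation:
    def test_rsm_equal_to_model_gives_maximal_tau(self):
        """tau-a of a binary model with itself is its ceiling: only
        diagonal/off-diagonal mixed pairs can be concordant, so the
        maximum is N*M / C(n,2) (= 24/45 for N=4), not 1."""
        model = rsa.subcategory_model()
        rsm = rsa.SplitRSM(model.matrix.copy(), ("a", "b", "c", "d"), 1)
        ceiling = 4 * 6 / (10 * 9 / 2)
        assert rsa.model_correlation(rsm, model) == pytest.approx(ceiling)
        assert rsa.model_correlation(rsm, model) == pytest.approx(
            brute_force_tau_a(rsa.rsm_model_vector(model.matrix),
                              rsa.rsm_model_vector(model.matrix))
        )

    def test_anti_model_gives_minimal_tau(self):
        model = rsa.subcategory_model()
        rsm = rsa.SplitRSM(1.0 - model.matrix, ("a", "b", "c", "d"), 1)
        assert rsa.model_correlation(rsm, model) == pytest.approx(-4 * 6 / 45)

    def test_three_by_three_matches_pair_counting_oracle(self):
        m = np.array([[0.9, 0.1, 0.2], [0.1, 0.8, 0.3], [0.2, 0.3, 0.7]])
        rsm = rsa.SplitRSM(m, ("a", "b", "c"), 1)
        model = rsa.ModelMatrix.categorical(3)
        x = rsa.rsm_model_vector(m)
        y = rsa.rsm_model_vector(model.matrix)
        assert rsa.model_correlation(rsm, model) == pytest.approx(
            brute_force_tau_a(x, y)
        )

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_tau_a_matches_oracle_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        x = rng.integers(-3, 4, n).astype(float)  # ties likely
        y = rng.integers(-3, 4, n).astype(float)
        assert rsa.kendall_tau_a(x, y) == pytest.approx(brute_force_tau_a(x, y))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(16)
        m = rng.uniform(0, 1, (4, 4))
        m = (m + m.T) / 2
        model = rsa.subcategory_model()
        t1 = rsa.model_correlation(rsa.SplitRSM(m, ("a", "b", "c", "d"), 1), model)
        t2 = rsa.model_correlation(
            rsa.SplitRSM(np.exp(3 * m), ("a", "b", "c", "d"), 1), model
        )
        assert t1 == pytest.approx(t2)

    def test_constant_rsm_rejected(self):
        rsm = rsa.SplitRSM(np.full((4, 4), 0.2), ("a", "b", "c", "d"), 1)
        with pytest.raises(ValueError, match="constant"):
            rsa.model_correlation(rsm, rsa.subcategory_model())


class TestGroupInference:
    def test_all_small_p_all_significant(self):
        rng = np.random.default_rng(17)
        vals = 1.0 + 0.01 * rng.standard_normal((10, 10))  # strongly > 0
        res = rsa.group_inference(vals, null_value=0.0)
        assert res.significant.all()
        assert (res.p_values < 0.001).all()

    def test_single_test_reduces_to_alpha_threshold(self):
        rng = np.random.default_rng(18)
        vals = rng.standard_normal((8, 1))
        res = rsa.group_inference(vals)
        assert res.significant[0] == (res.p_values[0] <= 0.05)

    def test_bh_flags_match_brute_force_oracle(self):
        from scipy import stats as ss

        rng = np.random.default_rng(19)
        shifts = np.array([0.9, 0.8, 0.7, 0.6, 0.0])
        vals = rng.standard_normal((6, 5)) * 0.5 + shifts
        res = rsa.group_inference(vals)
        oracle = brute_force_bh(res.p_values, alpha=0.05)
        assert np.array_equal(res.significant, oracle)
        # p-values themselves match a direct t-test
        direct = np.array([ss.ttest_1samp(vals[:, j], 0.0).pvalue for j in range(5)])
        assert np.allclose(res.p_values, direct)

    @pytest.mark.parametrize(
        "p_set", [(0.01, 0.02, 0.03, 0.04, 0.2), (0.04, 0.04, 0.04, 0.051, 0.9)]
    )
    def test_bh_oracle_on_fixed_p_values(self, p_set):
        from statsmodels.stats.multitest import multipletests

        flags = multipletests(list(p_set), alpha=0.05, method="fdr_bh")[0]
        assert np.array_equal(flags, brute_force_bh(p_set, 0.05))

    def test_zero_variance_column_flagged_degenerate(self):
        vals = np.column_stack([np.full(5, 0.3), np.random.default_rng(20).standard_normal(5)])
        res = rsa.group_inference(vals)
        assert res.degenerate[0] and not res.degenerate[1]
        assert not res.significant[0]


class TestHalfPartitions:
    def test_partitions_are_distinct_balanced_and_canonical(self):
        parts = rsa.half_partitions(8, 20, seed=21)
        seen = set()
        for a, b in parts:
            assert len(a) == len(b) == 4
            assert 0 in a  # canonical: half A contains run 0
            assert sorted(np.concatenate([a, b])) == list(range(8))
            seen.add(tuple(a))
        assert len(seen) == len(parts)

    def test_exhaustive_count(self):
        assert len(rsa.half_partitions(6, None, exhaustive=True)) == 10  # C(5,2)
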