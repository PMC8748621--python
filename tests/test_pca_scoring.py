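"""PCA scoring: eigenstructure, loadings, contribution rates, composite F."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from germdiv import (
    component_scores,
    composite_score,
    contribution_rates,
    correlation_eigen,
    loadings,
    pca_scores,
    rank_and_select,
    retain_components,
)

# Printed leading eigenvalues of the 29-trait correlation PCA
PRINTED_EIGENVALUES = np.array([6.570, 4.051, 2.048, 1.810, 1.566, 1.326, 1.302, 1.169, 1.097])


def _random_block(n, q, seed, corr=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, q))
    if corr:
        shared = rng.normal(size=(n, 1))
        X = np.sqrt(1 - corr) * X + np.sqrt(corr) * shared
    return pd.DataFrame(X, columns=[f"T{i}" for i in range(q)])


class TestCorrelationEigen:
    def test_two_traits_closed_form_one_plus_minus_r(self):
        block = _random_block(200, 2, seed=1, corr=0.4)
        r = np.corrcoef(block.T)[0, 1]
        w, _ = correlation_eigen(block)
        np.testing.assert_allclose(np.sort(w), np.sort([1 - r, 1 + r]), atol=1e-10)

    def test_eigenvalue_sum_is_trace_q(self):
        block = _random_block(100, 5, seed=2)
        w, _ = correlation_eigen(block)
        assert w.sum() == pytest.approx(5.0, abs=1e-10)

    def test_decomposition_reconstructs_correlation(self):
        block = _random_block(80, 5, seed=3, corr=0.3)
        w, V = correlation_eigen(block)
        R = np.corrcoef(block.to_numpy(), rowvar=False)
        np.testing.assert_allclose(V @ np.diag(w) @ V.T, R, atol=1e-8)

    def test_sign_convention_deterministic(self):
        block = _random_block(60, 4, seed=4)
        w1, V1 = correlation_eigen(block)
        w2, V2 = correlation_eigen(block)
        np.testing.assert_array_equal(V1, V2)
        for j in range(V1.shape[1]):
            assert V1[np.argmax(np.abs(V1[:, j])), j] > 0

    def test_matches_sklearn_cross_check(self):
        sklearn_decomposition = pytest.importorskip("sklearn.decomposition")
        block = _random_block(120, 6, seed=5, corr=0.3)
        w, _ = correlation_eigen(block)
        Z = (block - block.mean()) / block.std(ddof=1)
        p = sklearn_decomposition.PCA().fit(Z.to_numpy())
        # sklearn explained variance on z-scores = correlation eigenvalues (n-1 scaling)
        np.testing.assert_allclose(w, p.explained_variance_, atol=1e-8)


class TestLoadings:
    def test_scaling_arithmetic(self):
        L = loadings(np.array([4.0]), np.array([[0.5]]))
        assert L[0, 0] == pytest.approx(1.0)

    def test_column_sum_of_squares_equals_eigenvalue(self):
        block = _random_block(90, 6, seed=6, corr=0.2)
        w, V = correlation_eigen(block)
        L = loadings(w, V)
        np.testing.assert_allclose((L**2).sum(axis=0), w, atol=1e-8)

    def test_row_communalities_close_to_one(self):
        block = _random_block(90, 6, seed=7)
        w, V = correlation_eigen(block)
        L = loadings(w, V)
        np.testing.assert_allclose((L**2).sum(axis=1), 1.0, atol=1e-8)

    def test_negative_eigenvalue_beyond_tolerance_rejected(self):
        with pytest.raises(ValueError):
            loadings(np.array([-0.01]), np.array([[1.0]]))


class TestContributionRates:
    def test_printed_first_component(self):
        contrib, _ = contribution_rates(PRINTED_EIGENVALUES, q=29)
        assert contrib[0] == pytest.approx(22.655, abs=0.001)

    def test_printed_cumulative(self):
        _, cum = contribution_rates(PRINTED_EIGENVALUES, q=29)
        assert cum[-1] == pytest.approx(72.204, abs=0.01)
        assert (np.diff(cum) >= 0).all()

    def test_equal_eigenvalues_uniform_contribution(self):
        contrib, cum = contribution_rates(np.ones(8))
        np.testing.assert_allclose(contrib, 100 / 8)
        assert cum[-1] == pytest.approx(100.0)


class TestRetention:
    def test_kaiser_on_printed_eigenvalues(self):
        padded = np.concatenate([PRINTED_EIGENVALUES, np.full(20, 0.4)])
        assert retain_components(padded) == 9

    def test_kaiser_single_dominant(self):
        assert retain_components(np.array([3.0, 0.9, 0.1])) == 1

    def test_cumulative_rule_at_70_percent(self):
        # cumulative reaches 68.421% at k=8 and 72.204% at k=9
        assert retain_components(PRINTED_EIGENVALUES, rule="cumulative", threshold=70.0, q=29) == 9

    def test_fixed_rule(self):
        assert retain_components(PRINTED_EIGENVALUES, rule="fixed", k=4) == 4


class TestComponentScores:
    def test_zero_data_zero_scores(self):
        block = pd.DataFrame(np.zeros((3, 2)), columns=["a", "b"])
        L = np.array([[0.7, 0.1], [0.3, -0.5]])
        assert (component_scores(block, L, 2).to_numpy() == 0).all()

    def test_one_trait_arithmetic(self):
        block = pd.DataFrame({"a": [10.0]})
        s = component_scores(block, np.array([[0.5]]), 1)
        assert s.iloc[0, 0] == pytest.approx(5.0)

    def test_standardized_score_variance_equals_eigenvalue(self):
        block = _random_block(300, 5, seed=8, corr=0.4)
        w, V = correlation_eigen(block)
        L = loadings(w, V)
        s = component_scores(block, L, 5, mode="standardized")
        # direct-projection oracle: z-scores times v_j*sqrt(E_j) have sample
        # variance v_j' R v_j * E_j = E_j^2 exactly (Z'Z/(n-1) = R)
        Z = (block - block.mean()) / block.std(ddof=1)
        for j in range(5):
            direct = Z.to_numpy() @ L[:, j]
            np.testing.assert_allclose(s.iloc[:, j], direct, atol=1e-10)
            assert np.var(direct, ddof=1) == pytest.approx(w[j] ** 2, rel=1e-8)

    def test_trait_misalignment_rejected(self):
        block = pd.DataFrame(np.zeros((3, 2)), columns=["a", "b"])
        L = pd.DataFrame(np.eye(2), index=["b", "a"], columns=["PC1", "PC2"])
        with pytest.raises(ValueError):
            component_scores(block, L, 1)


class TestCompositeScore:
    WEIGHTS = PRINTED_EIGENVALUES / 29

    @pytest.mark.parametrize(
        "scores,expected",
        [
            # printed per-component scores of the two reference individuals
            ([-304.11, 951.20, -128.02, 246.84, 99.26, 66.99, 178.71, 251.41, 13.02], 97.41),
            ([-172.04, 603.65, -74.71, 149.23, 63.49, 63.30, 138.06, 147.87, 10.42], 68.26),
        ],
    )
    def test_published_reference_individuals(self, scores, expected):
        assert composite_score(np.array(scores), self.WEIGHTS) == pytest.approx(expected, abs=0.1)

    def test_zero_scores(self):
        assert composite_score(np.zeros(9), self.WEIGHTS) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            composite_score(np.zeros(3), self.WEIGHTS)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(a=st.floats(min_value=-10, max_value=10), seed=st.integers(0, 2**16))
    def test_linearity(self, a, seed):
        s = np.random.default_rng(seed).normal(size=9)
        f = composite_score(s, self.WEIGHTS)
        assert composite_score(a * s, self.WEIGHTS) == pytest.approx(a * f, abs=1e-9 * (1 + abs(f)))


class TestRankAndSelect:
    @staticmethod
    def _table(values, ids=None):
        ids = ids or [f"i{k}" for k in range(len(values))]
        return pd.DataFrame({"F1": values}, index=pd.Index(ids, name="id"))

    def test_basic_ranks(self):
        t = rank_and_select(self._table([3.0, 1.0, 2.0]), np.array([3.0, 1.0, 2.0]))
        assert list(t.table["rank"]) == [1, 3, 2]

    def test_above_median_selection_on_five_distinct(self):
        vals = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        t = rank_and_select(self._table(list(vals)), vals)
        assert int(t.table["selected"].sum()) == 2

    def test_rank_invariant_under_constant_shift(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=20)
        t1 = rank_and_select(self._table(list(vals)), vals)
        t2 = rank_and_select(self._table(list(vals + 100)), vals + 100)
        pd.testing.assert_series_equal(t1.table["rank"], t2.table["rank"])

    def test_ties_broken_by_id(self):
        t = rank_and_select(self._table([1.0, 1.0], ids=["b", "a"]), np.array([1.0, 1.0]))
        assert t.table.loc["a", "rank"] == 1 and t.table.loc["b", "rank"] == 2


class TestEndToEnd:
    def test_cohort_invariants(self, cohort151_blocks):
        result, scores = pca_scores(cohort151_blocks)
        assert result.eigenvalues.sum() == pytest.approx(29.0, abs=1e-8)
        assert result.contribution.sum() == pytest.approx(100.0, abs=1e-8)
        np.testing.assert_allclose(
            (result.loadings.to_numpy() ** 2).sum(axis=0), result.eigenvalues, atol=1e-8
        )
        assert sorted(scores.table["rank"]) == list(range(1, 152))

    def test_retained_count_invariant_to_trait_order(self, cohort151_blocks):
        block = cohort151_blocks.quantitative_block()
        reversed_cols = list(block.columns)[::-1]
        r1, _ = pca_scores(cohort151_blocks)
        w1, _ = correlation_eigen(block)
        w2, _ = correlation_eigen(block[reversed_cols])
        np.testing.assert_allclose(np.sort(w1), np.sort(w2), atol=1e-10)
        assert retain_components(w1) == retain_components(w2) == r1.retained
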