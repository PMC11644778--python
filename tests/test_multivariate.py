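"""Correlation screening, Holm adjustment, Mann-Whitney, PCA summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_matrix
from mossrisk.multivariate import (
    holm_adjust,
    mann_whitney_compare,
    pca_summary,
    spearman_holm,
)

p_vectors = st.lists(
    st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=30
)


class TestHolm:
    def test_step_down_hand_example(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.04]), [0.02, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.3]), [0.3])

    @given(p_vectors)
    def test_dominates_raw_and_capped_at_one(self, p):
        adjusted = holm_adjust(p)
        assert np.all(adjusted >= np.asarray(p) - 1e-15)
        assert np.all(adjusted <= 1.0)

    @given(p_vectors)
    def test_rejections_subset_of_unadjusted(self, p):
        adjusted = holm_adjust(p)
        assert np.all(np.asarray(p)[adjusted < 0.05] < 0.05)


class TestSpearmanHolm:
    def test_monotone_relation_gives_unit_rho(self):
        x = np.arange(1.0, 13.0)
        matrix = make_matrix(np.column_stack([x, np.exp(x)]))
        result = spearman_holm(matrix)
        assert result.rho[0, 1] == pytest.approx(1.0)

    def test_reversed_relation_gives_minus_one(self):
        x = np.arange(1.0, 13.0)
        matrix = make_matrix(np.column_stack([x, 1.0 / x]))
        assert spearman_holm(matrix).rho[0, 1] == pytest.approx(-1.0)

    def test_symmetry_unit_diagonal_and_dominance(self, georgia_survey):
        matrix, _ = georgia_survey
        result = spearman_holm(matrix)
        np.testing.assert_allclose(result.rho, result.rho.T)
        np.testing.assert_allclose(np.diag(result.rho), 1.0)
        assert np.all(np.abs(result.rho) <= 1.0 + 1e-12)
        off = ~np.eye(len(result.elements), dtype=bool)
        assert np.all(result.p_adjusted[off] >= result.p_raw[off] - 1e-15)

    def test_geogenic_block_correlations_in_band(self, georgia_survey):
        matrix, _ = georgia_survey
        result = spearman_holm(matrix)
        frame = result.rho_frame()
        block = ["Al", "Co", "Cr", "Fe", "V"]
        for a, b in itertools.combinations(block, 2):
            assert 0.7 <= frame.loc[a, b] <= 0.95
        # and all block pairs survive the Holm screen
        mask = pd.DataFrame(
            result.significant, index=result.elements, columns=result.elements
        )
        assert all(mask.loc[a, b] for a, b in itertools.combinations(block, 2))

    def test_invariant_under_monotone_transform_of_one_element(self, georgia_survey):
        matrix, _ = georgia_survey
        transformed = matrix.values.copy()
        transformed[:, 0] = np.log(transformed[:, 0])
        result_a = spearman_holm(matrix)
        result_b = spearman_holm(
            make_matrix(transformed, elements=matrix.elements,
                        site_ids=matrix.site_ids)
        )
        np.testing.assert_allclose(result_a.rho, result_b.rho, atol=1e-12)

    def test_exact_small_n_p_matches_enumeration(self):
        # n=6, untied: p = #{perms with |rho| >= |rho_obs|} / 6!
        values = np.column_stack(
            [[1, 2, 3, 4, 5, 6], [2, 1, 4, 3, 6, 5.0]]
        )
        result = spearman_holm(make_matrix(values))
        rho_obs = result.rho[0, 1]
        base = np.arange(6)
        count = 0
        for perm in itertools.permutations(range(6)):
            d2 = np.sum((np.array(perm) - base) ** 2)
            rho = 1 - 6 * d2 / (6 * 35)
            if abs(rho) >= abs(rho_obs) - 1e-12:
                count += 1
        assert result.p_raw[0, 1] == pytest.approx(count / 720)

    def test_constant_column_masked_not_significant(self):
        rng = np.random.default_rng(0)
        values = np.column_stack(
            [np.full(20, 2.0), rng.lognormal(size=20), rng.lognormal(size=20)]
        )
        with pytest.warns(UserWarning, match="constant"):
            result = spearman_holm(make_matrix(values))
        assert np.isnan(result.rho[0, 1])
        assert not result.significant[0, 1]


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        a = make_matrix([[1.0], [2.0], [3.0]], elements=["Pb"])
        result = mann_whitney_compare(a, a)
        assert result.table.loc[0, "p"] == pytest.approx(1.0)
        assert not result.table.loc[0, "significant"]

    def test_complete_separation_exact_p(self):
        a = make_matrix([[1.0], [2.0], [3.0]], elements=["Pb"])
        b = make_matrix([[10.0], [20.0], [30.0]], elements=["Pb"])
        result = mann_whitney_compare(a, b)
        row = result.table.iloc[0]
        assert row["u"] == 0.0
        assert row["p"] == pytest.approx(0.1)  # 2/20 rank assignments
        assert row["method"] == "exact"

    def test_u_statistics_sum_to_n_a_times_n_b(self):
        rng = np.random.default_rng(5)
        a = make_matrix(rng.lognormal(size=(8, 1)), elements=["Pb"])
        b = make_matrix(rng.lognormal(1.0, size=(6, 1)), elements=["Pb"])
        u_ab = mann_whitney_compare(a, b).table.loc[0, "u"]
        u_ba = mann_whitney_compare(b, a).table.loc[0, "u"]
        assert u_ab + u_ba == 8 * 6

    def test_agrees_with_brute_force_enumeration(self):
        # exhaust all C(8,4) rank splits for two untied samples of 4
        rng = np.random.default_rng(2)
        x = rng.permutation([1.0, 3.0, 6.0, 11.0])
        y = rng.permutation([2.0, 5.0, 7.0, 20.0])
        combined = np.concatenate([x, y])
        u_obs = sum((xi > yj) for xi in x for yj in y)
        null = []
        for idx in itertools.combinations(range(8), 4):
            xs = combined[list(idx)]
            ys = np.delete(combined, list(idx))
            null.append(sum((xi > yj) for xi in xs for yj in ys))
        null = np.asarray(null)
        mean_u = 4 * 4 / 2
        p_exact = np.mean(np.abs(null - mean_u) >= abs(u_obs - mean_u))
        a = make_matrix(x[:, None], elements=["Pb"])
        b = make_matrix(y[:, None], elements=["Pb"])
        result = mann_whitney_compare(a, b)
        assert result.table.loc[0, "p"] == pytest.approx(p_exact)

    def test_unshared_elements_skipped_with_warning(self):
        a = make_matrix(np.ones((3, 2)) + np.arange(3)[:, None],
                        elements=["Pb", "Cd"])
        b = make_matrix(np.ones((3, 1)) + np.arange(3)[:, None], elements=["Pb"])
        with pytest.warns(UserWarning, match="Cd"):
            result = mann_whitney_compare(a, b)
        assert list(result.table["element"]) == ["Pb"]

    def test_no_shared_elements_error(self):
        a = make_matrix([[1.0], [2.0], [3.0]], elements=["Pb"])
        b = make_matrix([[1.0], [2.0], [3.0]], elements=["Cd"])
        with pytest.raises(ValueError, match="share no elements"):
            mann_whitney_compare(a, b)


class TestPCA:
    def test_two_perfectly_correlated_columns_pc1_explains_all(self):
        x = np.linspace(1, 5, 30)
        matrix = make_matrix(np.column_stack([x, 3 * x]))
        result = pca_summary(matrix, n_components=2)
        assert result.variance_percent[0] == pytest.approx(100.0)

    def test_variance_shares_non_increasing_and_bounded(self, georgia_survey):
        matrix, _ = georgia_survey
        result = pca_summary(matrix, n_components=5, log_transform=True)
        shares = result.variance_percent
        assert np.all(np.diff(shares) <= 1e-9)
        assert shares.sum() <= 100.0 + 1e-9

    def test_loadings_orthonormal_scores_centered(self, georgia_survey):
        matrix, _ = georgia_survey
        result = pca_summary(matrix, n_components=3, log_transform=True)
        loadings = result.loadings.to_numpy()
        np.testing.assert_allclose(
            loadings.T @ loadings, np.eye(3), atol=1e-8
        )
        np.testing.assert_allclose(result.scores.mean(axis=0), 0.0, atol=1e-9)

    def test_contributions_are_squared_score_shares(self, georgia_survey):
        matrix, _ = georgia_survey
        result = pca_summary(matrix, n_components=2)
        np.testing.assert_allclose(result.contributions.sum(axis=0), 100.0)
        scores = result.scores.to_numpy()
        expected = 100 * scores[:, 0] ** 2 / np.sum(scores[:, 0] ** 2)
        np.testing.assert_allclose(result.contributions.iloc[:, 0], expected)

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        values = np.column_stack([np.full(25, 4.0), rng.lognormal(size=(25, 3)).reshape(25, 3)])
        with pytest.warns(UserWarning, match="constant"):
            result = pca_summary(make_matrix(values), n_components=2)
        assert "E0" not in result.loadings.index
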