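import warnings

import numpy as np
import pytest
from scipy import stats

from mixclust.ama import (
    AmaConfig,
    CrossTab,
    ama_distance_matrix,
    ama_similarity_matrix,
    diagonalize_crosstab,
    gamma_from_values,
    gk_gamma,
    nearest_psd_projection,
    nominal_nominal_similarity,
    nominal_vs_ranked_similarity,
    order_categories_by_response,
    spearman_similarity,
)
from mixclust.mixedio import SimilarityMatrix, VariableSpec
from mixclust.simulate import random_mixed_dataset

import _oracles
from conftest import make_dataset


class TestSpearman:
    def test_monotone_and_antitone_are_one(self):
        assert spearman_similarity([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert spearman_similarity([1, 2, 3], [30, 20, 10]) == pytest.approx(1.0)

    def test_hand_computed_rank_correlation(self):
        # ranks of y = (2,1,4,3); Pearson with (1,2,3,4) = 0.6
        assert spearman_similarity([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_constant_variable_warns_zero(self):
        with pytest.warns(UserWarning):
            assert spearman_similarity([1, 1, 1], [1, 2, 3]) == 0.0


class TestGamma:
    def test_perfect_concordance_and_discordance(self):
        assert gk_gamma(CrossTab(["a", "b"], ["x", "y"], [[10, 0], [0, 10]])) == 1.0
        assert gk_gamma(CrossTab(["a", "b"], ["x", "y"], [[0, 10], [10, 0]])) == -1.0

    def test_mixed_table_matches_pair_enumeration(self):
        counts = [[4, 2], [1, 3]]
        t = CrossTab(["a", "b"], ["x", "y"], counts)
        assert t.n_c == 12 and t.n_d == 2
        assert gk_gamma(t) == pytest.approx(10 / 14)
        assert gk_gamma(t) == pytest.approx(_oracles.naive_gamma_from_table(counts))

    def test_counts_match_enumeration_on_random_tables(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 6, size=(rng.integers(2, 5), rng.integers(2, 5)))
            t = CrossTab(
                [f"r{i}" for i in range(counts.shape[0])],
                [f"c{j}" for j in range(counts.shape[1])],
                counts,
            )
            oracle = _oracles.naive_gamma_from_table(counts)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                assert gk_gamma(t) == pytest.approx(oracle, abs=1e-12)

    def test_values_form_agrees_with_enumeration(self, rng):
        x = rng.integers(0, 4, size=30).astype(float)
        y = rng.integers(0, 3, size=30).astype(float)
        assert gamma_from_values(x, y) == pytest.approx(
            _oracles.naive_gamma(x, y), abs=1e-12
        )

    def test_no_pairs_warns_zero(self):
        with pytest.warns(UserWarning):
            assert gk_gamma(CrossTab(["a"], ["x", "y"], [[3, 4]])) == 0.0


class TestCategoryReordering:
    def test_orders_by_mean_rank_of_response(self):
        # means of y-ranks: A lowest, then C, then B -> A < C < B
        x = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        y = [1, 2, 3, 20, 21, 22, 10, 11, 12]
        assert order_categories_by_response(x, y) == ["A", "C", "B"]

    def test_already_ordered_unchanged(self):
        x = ["A", "A", "B", "B"]
        y = [1, 2, 3, 4]
        assert order_categories_by_response(x, y) == ["A", "B"]

    def test_tied_means_keep_original_order(self):
        x = ["B", "B", "A", "A"]
        y = [1, 4, 2, 3]
        assert order_categories_by_response(x, y) == ["B", "A"]


class TestNominalVsRanked:
    def test_block_structured_response_reorders_and_correlates(self):
        # y = 1..30; A on 1-10, C on 11-20, B on 21-30: gate passes,
        # order A < C < B, |Spearman| of ordered scores vs y.
        y = np.arange(1, 31, dtype=float)
        x = np.array(["A"] * 10 + ["C"] * 10 + ["B"] * 10)
        got = nominal_vs_ranked_similarity(x, y, y_scale="quantitative")
        scores = np.array([{"A": 0, "C": 1, "B": 2}[v] for v in x], dtype=float)
        oracle = abs(stats.spearmanr(scores, y).statistic)
        assert got == pytest.approx(oracle, abs=1e-12)
        # sqrt(between/total rank variance) for 3 balanced blocks ~ 0.943
        assert got > 0.9

    def test_independent_response_stays_small(self):
        rng = np.random.default_rng(5)
        sims = []
        for _ in range(200):
            x = rng.choice(["A", "B", "C"], size=200)
            y = rng.standard_normal(200)
            sims.append(nominal_vs_ranked_similarity(x, y))
        assert np.median(sims) < 0.1

    def test_single_category_warns_zero(self):
        with pytest.warns(UserWarning):
            assert nominal_vs_ranked_similarity(["A"] * 5, [1, 2, 3, 4, 5]) == 0.0

    def test_gate_passes_at_roughly_alpha_under_independence(self):
        # fraction of Kruskal-Wallis gates firing under the null ~ alpha
        rng = np.random.default_rng(11)
        alpha = 0.05
        n_rep = 500
        fired = 0
        for _ in range(n_rep):
            x = rng.choice(["A", "B", "C"], size=60)
            y = rng.standard_normal(60)
            groups = [y[x == c] for c in "ABC"]
            _, p = stats.kruskal(*groups)
            fired += p < alpha
        se = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(fired / n_rep - alpha) < 3 * se


class TestDiagonalize:
    def test_antidiagonal_table_flipped_to_gamma_one(self):
        t = CrossTab(["a", "b"], ["x", "y"], [[0, 5], [5, 0]])
        out = diagonalize_crosstab(t)
        assert abs(gk_gamma(out)) == pytest.approx(1.0)

    def test_diagonal_table_unchanged(self):
        t = CrossTab(["a", "b"], ["x", "y"], [[5, 0], [0, 5]])
        out = diagonalize_crosstab(t)
        assert out.row_levels == ["a", "b"] and out.col_levels == ["x", "y"]
        np.testing.assert_array_equal(out.counts, t.counts)

    def test_shuffled_identity_recovers_perfect_gamma(self, rng):
        for _ in range(10):
            k = int(rng.integers(3, 5))
            base = np.diag(rng.integers(3, 9, size=k))
            perm = rng.permutation(k)
            t = CrossTab(
                [f"r{i}" for i in range(k)], [f"c{j}" for j in range(k)], base[perm]
            )
            out = diagonalize_crosstab(t)
            assert abs(gk_gamma(out)) == pytest.approx(1.0)

    def test_heuristic_path_on_large_tables(self, rng):
        # both factors above the exhaustive cap: heuristic still helps
        k = 8
        base = np.diag(rng.integers(5, 12, size=k)).astype(float)
        base += rng.integers(0, 2, size=(k, k))
        perm, perm2 = rng.permutation(k), rng.permutation(k)
        t = CrossTab(
            [f"r{i}" for i in range(k)],
            [f"c{j}" for j in range(k)],
            base[np.ix_(perm, perm2)],
        )
        cfg = AmaConfig(max_exhaustive_categories=6)
        out = diagonalize_crosstab(t, cfg)
        assert abs(gk_gamma(out)) > abs(gk_gamma(t))


class TestNominalNominal:
    def test_antidiagonal_association_found(self):
        x = ["a"] * 5 + ["b"] * 5
        y = ["y"] * 5 + ["x"] * 5
        assert nominal_nominal_similarity(x, y) == pytest.approx(1.0)

    def test_exact_independence_gives_zero(self):
        x = ["a"] * 10 + ["b"] * 10
        y = (["x"] * 5 + ["y"] * 5) * 2
        assert nominal_nominal_similarity(x, y) == pytest.approx(0.0)

    def test_permuted_identity_three_levels(self):
        x = ["a"] * 50 + ["b"] * 50 + ["c"] * 50
        y = ["m"] * 50 + ["k"] * 50 + ["z"] * 50
        assert nominal_nominal_similarity(x, y) == pytest.approx(1.0)


class TestPsdProjection:
    def test_two_by_two_unchanged(self):
        s = SimilarityMatrix(["a", "b"], np.array([[1.0, 0.9], [0.9, 1.0]]))
        out = nearest_psd_projection(s)
        np.testing.assert_array_equal(out.values, s.values)

    def test_indefinite_chain_repaired(self):
        vals = np.array([[1.0, 0.9, 0.0], [0.9, 1.0, 0.9], [0.0, 0.9, 1.0]])
        assert np.linalg.eigvalsh(vals).min() < 0  # 1 - 0.9*sqrt(2)
        out = nearest_psd_projection(SimilarityMatrix(list("abc"), vals))
        assert np.linalg.eigvalsh(out.values).min() >= -1e-8
        np.testing.assert_array_equal(np.diag(out.values), 1.0)
        # projection moves entries by less than the violation magnitude
        viol = abs(np.linalg.eigvalsh(vals).min())
        assert np.abs(out.values - vals).max() < viol

    def test_identity_unchanged(self):
        s = SimilarityMatrix(list("abc"), np.eye(3))
        np.testing.assert_array_equal(nearest_psd_projection(s).values, np.eye(3))


class TestMatrixAssembly:
    def test_identical_nominal_variables_similarity_one(self):
        f = np.array(["A", "B", "A", "B", "A", "B"], dtype=object)
        ds = make_dataset(
            {"f": f, "g": f.copy()},
            [
                VariableSpec(name="f", scale="nominal"),
                VariableSpec(name="g", scale="nominal"),
            ],
        )
        s = ama_similarity_matrix(ds)
        assert s.values[0, 1] == pytest.approx(1.0)

    def test_quantitative_and_its_quartile_cut_strongly_similar(self, rng):
        n = 200
        v = rng.standard_normal(n)
        cut = np.digitize(v, np.quantile(v, [0.25, 0.5, 0.75]))
        levels = ("c1", "c2", "c3", "c4")
        ds = make_dataset(
            {
                "q": v,
                "o": np.array([levels[c] for c in cut], dtype=object),
            },
            [
                VariableSpec(name="q", scale="quantitative"),
                VariableSpec(name="o", scale="ordinal", levels=levels),
            ],
        )
        s = ama_similarity_matrix(ds)
        assert s.values[0, 1] >= 0.9

    def test_independent_variables_near_zero(self, rng):
        sims = []
        for _ in range(200):
            ds = make_dataset(
                {"a": rng.standard_normal(400), "b": rng.standard_normal(400)},
                [
                    VariableSpec(name="a", scale="quantitative"),
                    VariableSpec(name="b", scale="quantitative"),
                ],
            )
            sims.append(ama_similarity_matrix(ds).values[0, 1])
        assert np.median(sims) < 0.1

    def test_similarities_bounded_and_symmetric(self, rng):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds = random_mixed_dataset(rng, n=30, p=8, missing_fraction=0.1)
            s = ama_similarity_matrix(ds).values
        assert s.min() >= 0.0 and s.max() <= 1.0
        np.testing.assert_allclose(s, s.T, atol=0)

    def test_distances_are_sqrt_one_minus_similarity(self):
        f = np.array(["A", "B"] * 5, dtype=object)
        q = np.arange(10, dtype=float)
        ds = make_dataset(
            {"f": f, "q": q},
            [
                VariableSpec(name="f", scale="nominal"),
                VariableSpec(name="q", scale="quantitative"),
            ],
        )
        s = nearest_psd_projection(ama_similarity_matrix(ds))
        d = ama_distance_matrix(ds)
        np.testing.assert_allclose(
            d.values, np.sqrt(np.clip(1 - s.values, 0, None)), atol=1e-12
        )

    def test_triangle_inequality_after_projection(self, rng):
        for _ in range(5):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ds = random_mixed_dataset(rng, n=25, p=10)
                d = ama_distance_matrix(ds).values
            p = d.shape[0]
            for i in range(p):
                for j in range(p):
                    assert np.all(d[i, j] <= d[i, :] + d[:, j] + 1e-9)
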