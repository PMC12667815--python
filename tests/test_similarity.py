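"""Similarity registry, iSIM/eSIM counters, and the NSimilarity selector."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from divsel.similarity import (
    SIMILARITY_INDICES,
    NSimilaritySelector,
    esim_nary,
    isim_average,
    list_indices,
    modified_tanimoto,
    pairwise_similarity,
    pairwise_similarity_matrix,
    select_nsimilarity,
    similarity_to_distance,
)
from divsel.synthetic import gaussian_blobs, random_fingerprints

NAMED_TWELVE = [
    "austin_colwell", "baroni_urbani_buser", "consonni_todeschini", "faith",
    "gleason", "jaccard", "jaccard_0variant", "jaccard_tanimoto",
    "rogers_tanimoto", "russell_rao", "sokal_michener", "sokal_sneath",
]

binary_vec = st.lists(st.integers(0, 1), min_size=1, max_size=40)


class TestRegistry:
    def test_exactly_sixteen_indices(self):
        assert len(list_indices()) == 16

    def test_includes_the_twelve_named(self):
        assert set(NAMED_TWELVE) <= set(list_indices())

    @pytest.mark.parametrize("index", sorted(SIMILARITY_INDICES))
    def test_symmetric_and_maximal_at_identity(self, index, rng):
        for _ in range(20):
            d = int(rng.integers(1, 30))
            x = (rng.random(d) < 0.4).astype(float)
            y = (rng.random(d) < 0.4).astype(float)
            sxy = pairwise_similarity(x, y, index)
            assert sxy == pytest.approx(pairwise_similarity(y, x, index))
            assert pairwise_similarity(x, x, index) >= sxy - 1e-12
            assert -1e-12 <= sxy <= 1 + 1e-12

    def test_identity_is_one_for_unit_max_indices(self):
        x = np.array([1, 0, 1, 1, 0], dtype=float)
        for index in ("jaccard_tanimoto", "sokal_michener", "gleason",
                      "rogers_tanimoto", "sokal_sneath", "jaccard"):
            assert pairwise_similarity(x, x, index) == pytest.approx(1.0)


class TestPairwise:
    def test_jaccard_tanimoto_hand_counters(self):
        assert pairwise_similarity([1, 1, 0], [1, 0, 1], "jt") == pytest.approx(1 / 3)

    def test_austin_colwell_hand_value(self):
        # (a+d)/p = 3/4, arcsin(sqrt(3)/2) = pi/3 -> 2/3
        got = pairwise_similarity([1, 1, 0, 0], [1, 0, 0, 0], "austin_colwell")
        assert got == pytest.approx(2 / 3)

    def test_all_zero_vectors_follow_zero_denominator_rule(self):
        z = [0, 0, 0]
        assert pairwise_similarity(z, z, "jt") == 1.0
        assert pairwise_similarity(z, [1, 0, 0], "jt") == 0.0

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            pairwise_similarity([0.5, 1], [1, 0], "jt")

    def test_matrix_is_symmetric_with_unit_diagonal(self, rng):
        X = random_fingerprints(8, 16, seed=1)
        S = pairwise_similarity_matrix(X, "jt")
        assert np.allclose(S, S.T)
        assert np.allclose(np.diag(S), 1.0)


class TestModifiedTanimoto:
    def test_identity_is_one(self):
        x = np.array([1, 0, 1, 0], dtype=float)
        assert modified_tanimoto(x, x) == pytest.approx(1.0)

    def test_complement_is_zero(self):
        x = np.array([1, 0, 1, 0], dtype=float)
        assert modified_tanimoto(x, 1 - x) == pytest.approx(0.0)

    def test_hand_evaluated_value(self):
        # a=1, b=1, c=0, d=2, p_bar=3/8: (13/24)(1/2) + (11/24)(2/3) = 83/144
        got = modified_tanimoto([1, 1, 0, 0], [1, 0, 0, 0])
        assert got == pytest.approx(83 / 144)


class TestISim:
    def test_russell_rao_hand_value(self):
        assert isim_average([[1, 1], [1, 0], [0, 1]], "rr") == pytest.approx(1 / 3)

    def test_identical_rows_score_one(self):
        X = np.tile([1.0, 0.0, 1.0], (4, 1))
        for index in ("jt", "sm", "gleason"):
            assert isim_average(X, index) == pytest.approx(1.0)

    @pytest.mark.parametrize("index", ["russell_rao", "sokal_michener"])
    def test_exactly_mean_pairwise_for_linear_indices(self, index, rng):
        for _ in range(100):
            s = int(rng.integers(2, 26))
            d = int(rng.integers(1, 65))
            X = (rng.random((s, d)) < rng.uniform(0.1, 0.9)).astype(float)
            S = pairwise_similarity_matrix(X, index)
            brute = S[np.triu_indices(s, 1)].mean()
            assert isim_average(X, index) == pytest.approx(brute, abs=1e-12)

    def test_non_binary_input_is_hard_error(self):
        with pytest.raises(ValueError, match="binary"):
            isim_average([[0.2, 1.0], [1.0, 0.0]], "jt")


class TestESim:
    def test_identical_rows_score_one(self):
        X = np.tile([1.0, 0.0, 1.0], (5, 1))
        assert esim_nary(X, "jt") == pytest.approx(1.0)

    @pytest.mark.parametrize("index", sorted(SIMILARITY_INDICES))
    def test_collapses_to_pairwise_at_two_samples(self, index, rng):
        for _ in range(100 // 16 + 3):
            d = int(rng.integers(1, 40))
            x = (rng.random(d) < 0.5).astype(float)
            y = (rng.random(d) < 0.5).astype(float)
            esim = esim_nary(np.stack([x, y]), index)
            isim = isim_average(np.stack([x, y]), index)
            pair = pairwise_similarity(x, y, index)
            assert esim == pytest.approx(pair, abs=1e-12)
            assert isim == pytest.approx(pair, abs=1e-12)

    def test_counter_walkthrough_three_samples(self):
        # columns of [[1,1],[1,0],[0,1]] both have sum 2 of s=3: margin
        # 2k-s = 1 > 0 so both are 1-similarity columns, raw count a=2,
        # weight 1/3 each -> w_a = 2/3, no dissimilarity columns, hence
        # JT = w_a / a = (2/3)/2 = 1/3 (equal to the mean pairwise JT).
        assert esim_nary([[1, 1], [1, 0], [0, 1]], "jt") == pytest.approx(1 / 3)

    def test_threshold_turns_narrow_majorities_into_dissimilarity(self):
        X = np.array([[1, 1], [1, 0], [0, 1]], dtype=float)
        strict = esim_nary(X, "jt", coincidence_threshold=1.5)
        assert strict == pytest.approx(0.0)  # all columns become mismatches

    def test_preprocess_enables_real_valued_input(self, rng):
        X = rng.random((6, 4))
        value = esim_nary(X, "jt", preprocess=True)
        assert 0.0 <= value <= 1.0
        with pytest.raises(ValueError, match="binary"):
            esim_nary(X, "jt", preprocess=False)

    def test_constant_column_counts_as_fully_coincident(self):
        X = np.column_stack([np.full(4, 2.5), np.linspace(0, 1, 4)])
        with_const = esim_nary(X, "sokal_michener", preprocess=True)
        assert with_const > esim_nary(X[:, 1:], "sokal_michener", preprocess=True)


class TestSimilarityToDistance:
    @pytest.mark.parametrize("s,method,expected", [
        (1.0, "reverse", 0.0),
        (0.5, "reverse", 0.5),
        (0.75, "squared-root", 0.5),
        (0.5, "reciprocal", 1.0),
    ])
    def test_scalar_conversions(self, s, method, expected):
        assert similarity_to_distance(s, method) == pytest.approx(expected)

    def test_matrix_diagonal_forced_zero(self):
        S = np.array([[1.0, 0.5], [0.5, 0.9]])
        D = similarity_to_distance(S, "reverse")
        assert D[1, 1] == 0.0 and D[0, 1] == 0.5

    def test_reciprocal_rejects_zero_similarity(self):
        with pytest.raises(ValueError, match="reciprocal"):
            similarity_to_distance(0.0, "reciprocal")

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            similarity_to_distance(1.5, "reverse")


class TestNSimilaritySelector:
    def test_hand_example_starts_at_outlier(self):
        X = np.array([[1, 1, 1], [1, 1, 0], [0, 0, 1]], dtype=float)
        res = select_nsimilarity(X, 2, "jt")
        assert res.indices == [2, 1]

    def test_n_equals_s_returns_all(self):
        X = random_fingerprints(6, 12, seed=0)
        res = select_nsimilarity(X, 6)
        assert sorted(res.indices) == list(range(6))

    @pytest.mark.parametrize("engine", ["esim", "isim"])
    def test_engines_produce_valid_selections(self, engine):
        X = random_fingerprints(15, 24, seed=3)
        res = select_nsimilarity(X, 5, engine=engine)
        assert len(set(res.indices)) == 5

    def test_selected_set_less_similar_than_random_subsets(self, rng):
        X = random_fingerprints(20, 32, seed=5)
        S = pairwise_similarity_matrix(X, "jt")
        n = 5
        sel = select_nsimilarity(X, n, "jt").indices
        mean_sel = S[np.ix_(sel, sel)][np.triu_indices(n, 1)].mean()
        rmeans = []
        for _ in range(1000):
            ridx = rng.choice(20, n, replace=False)
            rmeans.append(S[np.ix_(ridx, ridx)][np.triu_indices(n, 1)].mean())
        assert mean_sel <= np.quantile(rmeans, 0.1)

    def test_periphery_preference_on_point_clouds(self):
        # low-dimensional clouds: similarity-minimizing selection should land
        # on convex-hull vertices more often than a uniform random subset
        # (compared against the exact expectation, since selection is
        # deterministic per dataset)
        from scipy.spatial import ConvexHull

        hull_hits_sel, expected_rand = 0, 0.0
        for seed in range(20):
            X, _ = gaussian_blobs(n_samples=30, centers=1, spread=1.0, seed=seed)
            hull = set(ConvexHull(X).vertices.tolist())
            n = 5
            sel = select_nsimilarity(X, n, "jt", preprocess=True).indices
            hull_hits_sel += len(hull & set(sel))
            expected_rand += n * len(hull) / 30
        assert hull_hits_sel > expected_rand

    def test_real_valued_requires_preprocess(self, rng):
        with pytest.raises(ValueError, match="preprocess"):
            select_nsimilarity(rng.random((6, 3)), 3)

    def test_estimator_contract(self):
        X = random_fingerprints(10, 16, seed=2)
        est = NSimilaritySelector(n_select=4).fit(X)
        assert est.transform(X).shape == (4, 16)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(x=binary_vec, y=binary_vec)
def test_jt_complements_tanimoto_distance(x, y):
    """1 − JT similarity equals the tanimoto distance metric used by core."""
    from divsel.base import tanimoto_distance

    n = min(len(x), len(y))
    x, y = np.array(x[:n], dtype=float), np.array(y[:n], dtype=float)
    if n == 0:
        return
    assert tanimoto_distance(x, y) == pytest.approx(
        1 - pairwise_similarity(x, y, "jt")
    )
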