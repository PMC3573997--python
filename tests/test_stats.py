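import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import squareform

from embryoflow import (
    DissimilarityMatrix,
    anosim,
    bray_curtis_matrix,
    nmds,
    pairwise_anosim,
    significance_code,
)
from embryoflow.stats import n_distinct_partitions, _enumerate_partitions


# ---------------------------------------------------------------- oracles

def brute_force_anosim_r(dist: np.ndarray, groups: np.ndarray) -> float:
    """Naive ANOSIM R straight from its definition, pair by pair."""
    n = len(groups)
    pairs, within = [], []
    for i in range(n):
        for j in range(i + 1, n):
            pairs.append(dist[i, j])
            within.append(groups[i] == groups[j])
    order = np.argsort(pairs, kind="stable")
    ranks = np.empty(len(pairs))
    # mid-ranks for ties, computed by explicit grouping
    sorted_vals = np.asarray(pairs)[order]
    k = 0
    while k < len(pairs):
        m = k
        while m + 1 < len(pairs) and sorted_vals[m + 1] == sorted_vals[k]:
            m += 1
        ranks[order[k : m + 1]] = (k + m) / 2 + 1
        k = m + 1
    within = np.asarray(within)
    rw = ranks[within].mean()
    rb = ranks[~within].mean()
    return (rb - rw) / (n * (n - 1) / 4)


def exhaustive_two_group_p(dist: np.ndarray, n_a: int) -> tuple[float, float]:
    """Exact p by enumerating every split of n into groups of n_a and n-n_a."""
    n = len(dist)
    obs = brute_force_anosim_r(dist, np.array([0] * n_a + [1] * (n - n_a)))
    seen = set()
    rs = []
    for comb in itertools.combinations(range(n), n_a):
        rest = frozenset(range(n)) - frozenset(comb)
        key = frozenset([frozenset(comb), rest])
        if key in seen:
            continue
        seen.add(key)
        g = np.ones(n, dtype=int)
        g[list(comb)] = 0
        rs.append(brute_force_anosim_r(dist, g))
    rs = np.asarray(rs)
    return obs, float(np.mean(rs >= obs - 1e-12))


def _random_dist(rng, n):
    d = squareform(rng.uniform(0.05, 1.0, n * (n - 1) // 2))
    return DissimilarityMatrix([f"i{k}" for k in range(n)], d)


# ------------------------------------------------------------ Bray-Curtis

class TestBrayCurtis:
    def test_identical_vectors_distance_zero(self):
        m = bray_curtis_matrix(np.array([[1.0, 2.0, 3.0]] * 2), labels=["a", "b"])
        assert m.values[0, 1] == 0.0

    def test_disjoint_support_distance_one(self):
        m = bray_curtis_matrix(np.array([[1.0, 0.0], [0.0, 1.0]]), labels=["a", "b"])
        assert m.values[0, 1] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # |2-1| + |1-1| over (2+1) + (1+1) = 1/5
        m = bray_curtis_matrix(np.array([[2.0, 1.0], [1.0, 1.0]]), labels=["a", "b"])
        assert m.values[0, 1] == pytest.approx(0.2)

    def test_all_zero_pair_raises_with_ids(self):
        mat = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 2.0]])
        with pytest.raises(ValueError, match="'a'.*'b'"):
            bray_curtis_matrix(mat, labels=["a", "b", "c"])

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            bray_curtis_matrix(np.array([[1.0, -0.1], [0.5, 0.5]]), labels=["a", "b"])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1),
           st.integers(min_value=2, max_value=10))
    def test_output_bounds_symmetry_diagonal(self, seed, n):
        rng = np.random.default_rng(seed)
        mat = rng.uniform(0.01, 5.0, size=(n, 6))
        m = bray_curtis_matrix(mat, labels=[str(i) for i in range(n)])
        assert np.all((m.values >= 0) & (m.values <= 1))
        np.testing.assert_allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0)


# ----------------------------------------------------------------- ANOSIM

class TestAnosim:
    def test_perfect_separation_two_groups_of_three(self, rng):
        # every between-pair larger than every within-pair -> R = 1, p = 1/10
        n = 6
        d = np.zeros((n, n))
        groups = np.array(["a"] * 3 + ["b"] * 3)
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = (
                    rng.uniform(0.7, 1.0) if groups[i] != groups[j]
                    else rng.uniform(0.1, 0.3)
                )
        res = anosim(DissimilarityMatrix(list("abcdef"), d), groups)
        assert res.exact
        assert res.R == pytest.approx(1.0, abs=1e-12)
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        assert res.n_permutations == 10

    def test_r_matches_brute_force_oracle(self, rng):
        for trial in range(5):
            n = 9
            dist = _random_dist(rng, n)
            groups = np.array(["a"] * 4 + ["b"] * 3 + ["c"] * 2)
            res = anosim(dist, groups)
            expected = brute_force_anosim_r(dist.values, groups)
            assert res.R == pytest.approx(expected, abs=1e-12)

    def test_r_matches_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import anosim as sk_anosim, DistanceMatrix

        dist = _random_dist(rng, 10)
        groups = ["a"] * 5 + ["b"] * 5
        res = anosim(dist, groups)
        sk = sk_anosim(DistanceMatrix(dist.values, ids=dist.labels), groups,
                       permutations=99)
        assert res.R == pytest.approx(sk["test statistic"], abs=1e-12)

    def test_monte_carlo_within_3se_of_exact(self, rng):
        dist = _random_dist(rng, 8)
        groups = np.array(["a"] * 4 + ["b"] * 4)
        mild = dist.values.copy()
        # add mild structure so p is away from both 0 and 1
        mild[:4, :4] *= 0.6
        mild[4:, 4:] *= 0.6
        np.fill_diagonal(mild, 0)
        dist = DissimilarityMatrix(dist.labels, (mild + mild.T) / 2)
        exact = anosim(dist, groups)
        assert exact.exact and exact.n_permutations == 35
        mc = anosim(dist, groups, n_permutations=50_000, seed=7, exhaustive_limit=1)
        assert not mc.exact
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / 50_000)
        assert abs(mc.p_value - exact.p_value) <= 3 * se + 1 / 50_001

    def test_null_r_centered_on_zero(self, rng):
        # random labels on a random matrix: R averages ~0 over resimulations
        rs = []
        for _ in range(1000):
            d = _random_dist(rng, 8)
            g = rng.permutation(["a"] * 4 + ["b"] * 4)
            rs.append(brute_force_anosim_r(d.values, g))
        assert abs(np.mean(rs)) < 0.05

    def test_single_member_group_rejected(self, rng):
        dist = _random_dist(rng, 5)
        with pytest.raises(ValueError, match=">= 2 members"):
            anosim(dist, ["a", "a", "b", "b", "c"])

    def test_one_group_rejected(self, rng):
        dist = _random_dist(rng, 4)
        with pytest.raises(ValueError, match="2 groups"):
            anosim(dist, ["a"] * 4)

    def test_seeded_monte_carlo_reproducible(self, rng):
        dist = _random_dist(rng, 8)
        groups = ["a"] * 4 + ["b"] * 4
        r1 = anosim(dist, groups, n_permutations=500, seed=42, exhaustive_limit=1)
        r2 = anosim(dist, groups, n_permutations=500, seed=42, exhaustive_limit=1)
        assert (r1.R, r1.p_value) == (r2.R, r2.p_value)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_r_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        dist = _random_dist(rng, 7)
        groups = ["a"] * 3 + ["b"] * 4
        base = anosim(dist, groups)
        # strictly monotone map of the dissimilarities preserves ranks
        a, b = rng.uniform(0.5, 3.0), rng.uniform(0.1, 2.0)
        warped = np.tanh(a * dist.values) ** b
        np.fill_diagonal(warped, 0)
        res = anosim(DissimilarityMatrix(dist.labels, warped), groups)
        assert res.R == pytest.approx(base.R, abs=1e-12)
        assert res.p_value == pytest.approx(base.p_value, abs=1e-12)


class TestPartitionEnumeration:
    @pytest.mark.parametrize("sizes,expected", [
        ([3, 3], 10), ([4, 4], 35), ([2, 3], 10), ([6, 6], 462),
        ([2, 2, 2], 15), ([2, 3, 4], 1260),
    ])
    def test_partition_counts(self, sizes, expected):
        assert n_distinct_partitions(sizes) == expected
        parts = list(_enumerate_partitions(sum(sizes), sizes))
        assert len(parts) == expected
        # all partitions distinct as set-of-frozensets
        keys = set()
        for labels in parts:
            key = frozenset(
                frozenset(np.flatnonzero(labels == g)) for g in np.unique(labels)
            )
            keys.add(key)
        assert len(keys) == expected


# --------------------------------------------------------------- pairwise

class TestPairwiseAnosim:
    def test_three_groups_three_rows(self, rng):
        dist = _random_dist(rng, 9)
        table = pairwise_anosim(dist, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert len(table) == 3
        assert {(r[0], r[1]) for r in table.rows} == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_five_groups_ten_rows(self, rng):
        dist = _random_dist(rng, 15)
        groups = [g for g in "abcde" for _ in range(3)]
        table = pairwise_anosim(dist, groups, n_permutations=99, seed=0)
        assert len(table) == 10

    def test_degenerate_identical_vectors_ns(self):
        # two groups of replicated identical vectors: all distances zero,
        # ranks fully tied, R = 0, not significant
        mat = np.vstack([[1.0, 2.0, 3.0]] * 6)
        dist = bray_curtis_matrix(mat, labels=[f"i{k}" for k in range(6)])
        table = pairwise_anosim(dist, ["a"] * 3 + ["b"] * 3)
        (_, _, r, p, code) = table.rows[0]
        assert r == pytest.approx(0.0, abs=1e-12)
        assert code == "ns"

    def test_significance_codes(self):
        assert significance_code(0.0005) == "***"
        assert significance_code(0.005) == "**"
        assert significance_code(0.05) == "*"
        assert significance_code(0.2) == "ns"


# ------------------------------------------------------------------- nMDS

class TestNmds:
    def test_three_points_embed_exactly(self):
        d = np.array([[0, 1.0, 1.2], [1.0, 0, 0.8], [1.2, 0.8, 0]])
        emb = nmds(DissimilarityMatrix(["a", "b", "c"], d), seed=0)
        assert emb.stress < 1e-6

    def test_planar_configuration_recovers_distance_ranks(self):
        # hand-placed points whose 15 pairwise distances are well separated,
        # so the isotonic fit never pools neighbouring ranks into tied blocks
        pts = np.array([
            [0.0, 0.0], [1.0, 0.2], [3.1, 0.9], [0.4, 5.3], [7.9, 2.1],
            [5.0, 9.0],
        ])
        d = np.hypot(
            pts[:, None, 0] - pts[None, :, 0], pts[:, None, 1] - pts[None, :, 1]
        )
        emb = nmds(DissimilarityMatrix([str(i) for i in range(6)], d),
                   n_restarts=30, max_iter=1000, tol=1e-11, seed=1)
        assert emb.stress < 1e-3
        iu = np.triu_indices(6, 1)
        emb_d = np.hypot(
            emb.coordinates[:, None, 0] - emb.coordinates[None, :, 0],
            emb.coordinates[:, None, 1] - emb.coordinates[None, :, 1],
        )
        # the embedding must be weakly monotone in the input distances: the
        # isotonic fit may pool neighbouring ranks into exact ties, but no
        # pair may be strictly inverted
        order = np.argsort(d[iu])
        ordered = emb_d[iu][order]
        slack = 1e-3 * ordered.max()
        assert np.all(np.diff(ordered) >= -slack)

    def test_duplicated_individual_coalesces(self, rng):
        pts = rng.uniform(0, 10, (5, 2))
        pts = np.vstack([pts, pts[0]])  # duplicate the first point
        d = np.hypot(
            pts[:, None, 0] - pts[None, :, 0], pts[:, None, 1] - pts[None, :, 1]
        )
        emb = nmds(DissimilarityMatrix([str(i) for i in range(6)], d),
                   n_restarts=30, seed=2)
        gap = np.hypot(*(emb.coordinates[0] - emb.coordinates[5]))
        scale = np.abs(emb.coordinates).max()
        assert gap < 1e-3 * max(scale, 1.0)

    def test_too_few_points_rejected(self, rng):
        d = _random_dist(rng, 2)
        with pytest.raises(ValueError, match="at least 3"):
            nmds(d, n_dims=2)
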