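"""Multivariate comparison of spectral fingerprints.

Individuals are compared through Bray-Curtis dissimilarities of their
binned log-energy feature vectors.  Group structure is tested with ANOSIM
(Analysis of Similarities, Clarke 1993): the statistic

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4)

ranges over [-1, 1], with R near 0 under the null of no group structure.
Its permutation null distribution is enumerated exhaustively — over the
distinct set partitions of the individuals into groups of the observed
sizes — whenever that enumeration is small enough, otherwise approximated
by seeded Monte-Carlo label shuffles.  Ordination for plotting uses
non-metric MDS (iterative majorization with isotonic regression on the
dissimilarity ranks), quality reported as Kruskal stress-1.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.manifold import smacof

from .spectral import SpectralFeatureVector

__all__ = [
    "DissimilarityMatrix",
    "AnosimResult",
    "MdsEmbedding",
    "PairwiseTable",
    "bray_curtis_matrix",
    "anosim",
    "pairwise_anosim",
    "nmds",
    "significance_code",
]

#: Beyond this many distinct group partitions, fall back to Monte-Carlo.
EXHAUSTIVE_LIMIT = 200_000
DEFAULT_PERMUTATIONS = 9_999


@dataclass
class DissimilarityMatrix:
    """Symmetric Bray-Curtis dissimilarities among labelled individuals."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match the number of labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValueError("dissimilarity matrix must have a zero diagonal")

    def __len__(self) -> int:
        return len(self.labels)

    def submatrix(self, idx: np.ndarray) -> "DissimilarityMatrix":
        idx = np.asarray(idx)
        return DissimilarityMatrix(
            labels=[self.labels[i] for i in idx],
            values=self.values[np.ix_(idx, idx)],
        )


@dataclass
class AnosimResult:
    R: float
    p_value: float
    n_permutations: int
    exact: bool
    seed: int | None
    group_sizes: dict[str, int]


@dataclass
class MdsEmbedding:
    coordinates: np.ndarray  # (n, n_dims)
    stress: float            # Kruskal stress-1
    n_restarts: int
    seed: int | None
    converged: bool = True
    labels: list[str] | None = None


@dataclass
class PairwiseTable:
    """Rows of (group_a, group_b, R, p, significance code)."""

    rows: list[tuple[str, str, float, float, str]]

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.rows,
            columns=["group_a", "group_b", "R", "p_value", "significance"],
        )


def significance_code(p: float) -> str:
    """Conventional star coding: *** <=0.001, ** <=0.01, * <=0.05, else ns."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def bray_curtis_matrix(features: list[SpectralFeatureVector] | np.ndarray,
                       labels: list[str] | None = None) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarity d(x,y) = sum|x-y| / sum(x+y) between all pairs.

    Accepts either a list of :class:`SpectralFeatureVector` or a plain
    (n_individuals, n_features) non-negative array plus labels.

    Raises
    ------
    ValueError
        On fewer than 2 vectors, length mismatch, negative entries, or a
        pair of all-zero vectors (whose distance is undefined); the error
        names the offending pair.
    """
    if labels is None:
        if not all(isinstance(f, SpectralFeatureVector) for f in features):
            raise TypeError("need SpectralFeatureVectors, or an array plus labels")
        labels = [f.individual_id for f in features]
        mat = np.vstack([f.values for f in features])
    else:
        mat = np.asarray(features, dtype=np.float64)
    if mat.ndim != 2 or len(mat) < 2:
        raise ValueError("need at least 2 feature vectors of equal length")
    if np.any(mat < 0):
        raise ValueError("Bray-Curtis requires non-negative feature values")
    zero = ~mat.any(axis=1)
    if np.count_nonzero(zero) >= 2:
        bad = [labels[i] for i in np.flatnonzero(zero)[:2]]
        raise ValueError(
            f"distance between all-zero vectors is undefined "
            f"(individuals {bad[0]!r} and {bad[1]!r})"
        )
    d = squareform(pdist(mat, metric="braycurtis"))
    return DissimilarityMatrix(labels=list(labels), values=d)


def _anosim_r(condensed_ranks: np.ndarray, within_mask: np.ndarray, n: int) -> float:
    r_within = condensed_ranks[within_mask].mean()
    r_between = condensed_ranks[~within_mask].mean()
    return (r_between - r_within) / (n * (n - 1) / 4.0)


def _within_mask(groups: np.ndarray) -> np.ndarray:
    """Condensed-form boolean mask of within-group pairs."""
    n = len(groups)
    i, j = np.triu_indices(n, k=1)
    return groups[i] == groups[j]


def n_distinct_partitions(sizes: list[int]) -> int:
    """Distinct set partitions of sum(sizes) items into blocks of these sizes."""
    n = sum(sizes)
    total = math.factorial(n)
    for s in sizes:
        total //= math.factorial(s)
    for count in _size_multiplicities(sizes).values():
        total //= math.factorial(count)
    return total


def _size_multiplicities(sizes: list[int]) -> dict[int, int]:
    out: dict[int, int] = {}
    for s in sizes:
        out[s] = out.get(s, 0) + 1
    return out


def _partitions_fixed_size(items: tuple[int, ...], size: int, m: int):
    """Unordered partitions of items into m blocks of equal ``size``.

    Duplicates are avoided by anchoring each block on the smallest
    remaining item.
    """
    if m == 0:
        yield []
        return
    first, rest = items[0], items[1:]
    for comb in itertools.combinations(rest, size - 1):
        block = (first,) + comb
        remaining = tuple(x for x in rest if x not in comb)
        for tail in _partitions_fixed_size(remaining, size, m - 1):
            yield [block] + tail


def _enumerate_partitions(n: int, sizes: list[int]):
    """All distinct partitions of range(n) into unlabeled blocks of the
    given sizes, yielded as group-index vectors of length n."""
    classes = sorted(_size_multiplicities(sizes).items(), reverse=True)

    def recurse(remaining: tuple[int, ...], cls_idx: int, assigned: list[list[tuple[int, ...]]]):
        if cls_idx == len(classes):
            yield [blk for cls_blocks in assigned for blk in cls_blocks]
            return
        size, mult = classes[cls_idx]
        take = size * mult
        for chosen in itertools.combinations(remaining, take):
            rest = tuple(x for x in remaining if x not in chosen)
            for blocks in _partitions_fixed_size(chosen, size, mult):
                yield from recurse(rest, cls_idx + 1, assigned + [blocks])

    for blocks in recurse(tuple(range(n)), 0, []):
        labels = np.empty(n, dtype=np.int64)
        for g, block in enumerate(blocks):
            labels[list(block)] = g
        yield labels


def anosim(dist: DissimilarityMatrix, groups: list[str] | np.ndarray,
           n_permutations: int = DEFAULT_PERMUTATIONS,
           seed: int | None = None,
           exhaustive_limit: int = EXHAUSTIVE_LIMIT) -> AnosimResult:
    """ANOSIM permutation test of group structure in a dissimilarity matrix.

    All off-diagonal dissimilarities are ranked ascending (mid-ranks for
    ties) and R contrasts mean between- and within-group ranks.  When the
    number of distinct partitions of the individuals into groups of the
    observed sizes is at most ``exhaustive_limit`` the null distribution
    is enumerated exactly and p = #{R_perm >= R_obs} / total (the observed
    partition is one of those enumerated); otherwise ``n_permutations``
    seeded label shuffles give p = (#{R_perm >= R_obs} + 1) / (n_perm + 1).

    Raises
    ------
    ValueError
        If there are fewer than 2 groups or any group has fewer than 2
        members.
    """
    groups = np.asarray(groups)
    n = len(dist)
    if len(groups) != n:
        raise ValueError("one group label per individual is required")
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if np.any(counts < 2):
        small = uniq[counts < 2][0]
        raise ValueError(f"every group needs >= 2 members; group {small!r} has "
                         f"{int(counts[counts < 2][0])}")

    condensed = squareform(dist.values, checks=False)
    ranks = rankdata(condensed)  # mid-ranks for ties
    gidx = np.searchsorted(uniq, groups)
    iu, ju = np.triu_indices(n, k=1)
    denom = n * (n - 1) / 4.0
    grand = ranks.mean()

    def r_of(labels: np.ndarray) -> float:
        within = labels[iu] == labels[ju]
        r_within = ranks[within].mean()
        m = len(ranks)
        n_w = within.sum()
        r_between = (grand * m - r_within * n_w) / (m - n_w)
        return (r_between - r_within) / denom

    r_obs = r_of(gidx)
    sizes = counts.tolist()
    total = n_distinct_partitions(sizes)
    if total <= exhaustive_limit:
        hits = 0
        for labels in _enumerate_partitions(n, sizes):
            if r_of(labels) >= r_obs - 1e-12:
                hits += 1
        p = hits / total
        return AnosimResult(
            R=float(r_obs), p_value=float(p), n_permutations=total,
            exact=True, seed=seed,
            group_sizes={str(u): int(c) for u, c in zip(uniq, counts)},
        )
    rng = np.random.default_rng(seed)
    hits = 0
    perm = gidx.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm)
        if r_of(perm) >= r_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return AnosimResult(
        R=float(r_obs), p_value=float(p), n_permutations=n_permutations,
        exact=False, seed=seed,
        group_sizes={str(u): int(c) for u, c in zip(uniq, counts)},
    )


def pairwise_anosim(dist: DissimilarityMatrix, groups: list[str] | np.ndarray,
                    n_permutations: int = DEFAULT_PERMUTATIONS,
                    seed: int | None = None,
                    bonferroni: bool = False) -> PairwiseTable:
    """ANOSIM on every unordered pair of groups (sub-matrix per pair).

    Significance stars follow the conventional thresholds; p-values are
    reported without multiplicity adjustment unless ``bonferroni`` is set.
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups for pairwise comparison")
    n_tests = len(uniq) * (len(uniq) - 1) // 2
    rows = []
    for a, b in itertools.combinations(uniq, 2):
        idx = np.flatnonzero((groups == a) | (groups == b))
        res = anosim(dist.submatrix(idx), groups[idx],
                     n_permutations=n_permutations, seed=seed)
        p = min(res.p_value * n_tests, 1.0) if bonferroni else res.p_value
        rows.append((str(a), str(b), res.R, p, significance_code(p)))
    return PairwiseTable(rows=rows)


def nmds(dist: DissimilarityMatrix, n_dims: int = 2, n_restarts: int = 20,
         max_iter: int = 300, tol: float = 1e-7,
         seed: int | None = None) -> MdsEmbedding:
    """Non-metric MDS of a dissimilarity matrix, best of several restarts.

    Kruskal stress-1 is minimized by SMACOF majorization alternated with
    isotonic regression on the dissimilarity ranks; each restart starts
    from a fresh seeded random configuration and the lowest-stress
    solution is returned.
    """
    n = len(dist)
    if n < n_dims + 1:
        raise ValueError(f"need at least {n_dims + 1} individuals for "
                         f"{n_dims}-D ordination, got {n}")
    coords, stress, n_iter = smacof(
        dist.values, metric=False, n_components=n_dims, init=None,
        n_init=n_restarts, max_iter=max_iter, eps=tol,
        random_state=seed, normalized_stress=True,
        return_n_iter=True,
    )
    return MdsEmbedding(
        coordinates=coords, stress=float(stress), n_restarts=n_restarts,
        seed=seed, converged=n_iter < max_iter, labels=list(dist.labels),
    )
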