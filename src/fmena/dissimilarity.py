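"""Dissimilarity matrices and permutation tests on them.

Implements the three classical permutation tests for group structure on
a distance matrix — PERMANOVA (pseudo-F from distance-based sums of
squares), ANOSIM (rank-based R), and MRPP (weighted mean within-group
distance delta) — with free whole-sample label permutation and the
add-observed p-value convention p = (1 + #{as-or-more-extreme}) /
(n_perm + 1).  Small designs can be evaluated by exhaustive enumeration
of all distinct labelings.

Distances: Euclidean, Bray-Curtis, and the Morisita-Horn overlap
distance ("Horn" in community-ecology tables),

    d_MH(x, y) = 1 - 2 * sum(x*y) / ((sum(x^2)/X^2 + sum(y^2)/Y^2) * X * Y)

with X = sum(x), Y = sum(y).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

METRICS = ("euclidean", "bray", "horn")


@dataclass
class DissimilarityMatrix:
    values: np.ndarray  # n x n symmetric, zero diagonal
    ids: list[str]
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        if (v < -1e-12).any():
            raise ValueError("negative distances")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def _morisita_horn(x: np.ndarray, y: np.ndarray) -> float:
    X, Y = x.sum(), y.sum()
    if X == 0 or Y == 0:
        raise ValueError("all-zero sample profile: Horn distance undefined")
    simpson = (x @ x) / X**2 + (y @ y) / Y**2
    return 1.0 - 2.0 * (x @ y) / (simpson * X * Y)


def distance_matrix(profiles: pd.DataFrame, metric: str) -> DissimilarityMatrix:
    """Pairwise distances between sample rows of ``profiles``.

    ``profiles`` is samples x features.  Bray-Curtis and Horn require
    non-negative abundances and at least one positive value per sample.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    if len(profiles) < 2:
        raise ValueError("need >= 2 samples")
    x = profiles.to_numpy(dtype=float)
    if metric in ("bray", "horn"):
        if (x < 0).any():
            raise ValueError(f"{metric} requires non-negative abundances")
        if (x.sum(axis=1) == 0).any():
            bad = profiles.index[x.sum(axis=1) == 0].tolist()
            raise ValueError(f"all-zero samples for {metric}: {bad}")
    if metric == "euclidean":
        d = pdist(x, metric="euclidean")
    elif metric == "bray":
        d = pdist(x, metric="braycurtis")
    else:
        d = pdist(x, metric=_morisita_horn)
    return DissimilarityMatrix(squareform(d), [str(i) for i in profiles.index], metric)


@dataclass
class PermTestResult:
    test: str  # mrpp | anosim | permanova
    statistic: float  # delta, R, or pseudo-F
    p: float
    n_permutations: int
    scheme: str  # "free" or "exhaustive"

    @property
    def statistic_name(self) -> str:
        return {"mrpp": "delta", "anosim": "R", "permanova": "F"}[self.test]


def _check_groups(D: DissimilarityMatrix, groups: np.ndarray) -> list[np.ndarray]:
    if len(groups) != D.n:
        raise ValueError("group labels must match the distance matrix")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    if (counts < 2).any():
        small = labels[counts < 2].tolist()
        raise ValueError(f"groups with a single sample: {small}")
    return [np.flatnonzero(groups == g) for g in labels]


def _permanova_F(d2: np.ndarray, groups: np.ndarray) -> float:
    """Pseudo-F from squared distances and group labels."""
    n = d2.shape[0]
    labels = np.unique(groups)
    a = len(labels)
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in labels:
        idx = np.flatnonzero(groups == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def _anosim_R(rank_matrix: np.ndarray, groups: np.ndarray) -> float:
    """ANOSIM R from a full matrix of mid-ranked distances."""
    n = rank_matrix.shape[0]
    same = groups[:, None] == groups[None, :]
    iu = np.triu_indices(n, 1)
    within = rank_matrix[iu][same[iu]]
    between = rank_matrix[iu][~same[iu]]
    return (between.mean() - within.mean()) / (n * (n - 1) / 4.0)


def _mrpp_delta(d: np.ndarray, groups: np.ndarray) -> float:
    """Weighted mean within-group distance."""
    n = d.shape[0]
    delta = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        sub = d[np.ix_(idx, idx)]
        within = sub[np.triu_indices(len(idx), 1)]
        delta += (len(idx) / n) * within.mean()
    return delta


def _distinct_labelings(groups: np.ndarray):
    """All distinct orderings of the label multiset (small n only)."""
    seen = set()
    for perm in itertools.permutations(groups):
        if perm not in seen:
            seen.add(perm)
            yield np.array(perm)


def _perm_test(
    stat_fn,
    base: np.ndarray,
    groups: np.ndarray,
    n_perm: int,
    seed: int | None,
    smaller_is_extreme: bool,
    exact: bool,
) -> tuple[float, float, int, str]:
    observed = stat_fn(base, groups)
    if exact:
        stats_all = [stat_fn(base, g) for g in _distinct_labelings(groups)]
        stats_all = np.array(stats_all)
        if smaller_is_extreme:
            count = int((stats_all <= observed + 1e-12).sum())
        else:
            count = int((stats_all >= observed - 1e-12).sum())
        return observed, count / len(stats_all), len(stats_all), "exhaustive"
    rng = np.random.default_rng(seed)
    count = 0
    g = groups.copy()
    for _ in range(n_perm):
        rng.shuffle(g)
        s = stat_fn(base, g)
        if smaller_is_extreme:
            count += s <= observed + 1e-12
        else:
            count += s >= observed - 1e-12
    p = (1 + count) / (n_perm + 1)
    return observed, p, n_perm, "free"


def permanova(
    D: DissimilarityMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    exact: bool = False,
) -> PermTestResult:
    """Permutational multivariate ANOVA (pseudo-F) on a distance matrix.

    p is one-sided (large F extreme).  ``exact=True`` enumerates all
    distinct labelings instead of sampling (small designs only).
    """
    groups = np.asarray(groups)
    _check_groups(D, groups)
    d2 = D.values**2
    F, p, nperm, scheme = _perm_test(_permanova_F, d2, groups, n_perm, seed, False, exact)
    return PermTestResult("permanova", F, p, nperm, scheme)


def anosim(
    D: DissimilarityMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    exact: bool = False,
) -> PermTestResult:
    """Analysis of similarity: rank-based R with mid-ranks for ties."""
    groups = np.asarray(groups)
    _check_groups(D, groups)
    ranks = squareform(rankdata(D.condensed()), checks=False)
    R, p, nperm, scheme = _perm_test(_anosim_R, ranks, groups, n_perm, seed, False, exact)
    return PermTestResult("anosim", R, p, nperm, scheme)


def mrpp(
    D: DissimilarityMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    exact: bool = False,
) -> PermTestResult:
    """Multiple response permutation procedure (small delta = tight groups)."""
    groups = np.asarray(groups)
    _check_groups(D, groups)
    delta, p, nperm, scheme = _perm_test(_mrpp_delta, D.values, groups, n_perm, seed, True, exact)
    return PermTestResult("mrpp", delta, p, nperm, scheme)


def contrast_table(
    profiles: pd.DataFrame,
    groups,
    metrics=METRICS,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """All three tests under every metric, one row per metric.

    The table mirrors the conventional significance-test layout: columns
    for each test's statistic and p value.
    """
    rows = []
    for i, metric in enumerate(metrics):
        D = distance_matrix(profiles, metric)
        sub_seed = None if seed is None else seed + i
        r_m = mrpp(D, groups, n_perm, sub_seed)
        r_a = anosim(D, groups, n_perm, sub_seed)
        r_p = permanova(D, groups, n_perm, sub_seed)
        rows.append(
            {
                "metric": metric,
                "mrpp_delta": r_m.statistic,
                "mrpp_p": r_m.p,
                "anosim_R": r_a.statistic,
                "anosim_p": r_a.p,
                "adonis_F": r_p.statistic,
                "adonis_p": r_p.p,
            }
        )
    return pd.DataFrame(rows)
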