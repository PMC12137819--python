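"""Distances, binary relevance lists, and (mean) average precision.

Average precision here is the conventional non-interpolated form: the mean
of precision@k over the ranks k that hold a correct match, equivalently the
recall-increment weighted sum sum_k (R_k - R_{k-1}) P_k with R_0 = 0. For a
query drawn from a group of M replicates ranked against N reference
profiles, the list has n_pos = M - 1 correct matches among
n_total = (M - 1) + N candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "RelevanceList",
    "APResult",
    "MAPResult",
    "pairwise_distance",
    "distance_to",
    "rank_relevance",
    "average_precision",
    "precision_at_k",
    "mean_ap",
]

_METRICS = ("cosine", "euclidean", "pearson")


@dataclass
class RelevanceList:
    """An ordered binary relevance list for one query.

    ``ranks[k]`` is 1 when rank ``k`` (0-based, most similar first) holds a
    correct match. ``n_pos`` is the number of correct matches (M - 1) and
    ``n_total`` the list length ((M - 1) + N).
    """

    ranks: np.ndarray
    n_pos: int
    n_total: int

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=np.int8)
        if self.ranks.ndim != 1 or len(self.ranks) != self.n_total:
            raise ValueError("n_total must equal len(ranks)")
        if int(self.ranks.sum()) != self.n_pos:
            raise ValueError("sum(ranks) must equal n_pos")
        if not (1 <= self.n_pos < self.n_total):
            raise ValueError("need 1 <= n_pos < n_total")


@dataclass
class APResult:
    """Average precision for one query profile."""

    query_id: object
    ap: float
    n_pos: int
    n_total: int
    p_value: float | None = None


@dataclass
class MAPResult:
    """Mean AP over a query group, with permutation significance."""

    group: object
    map: float
    members: list[APResult] = field(default_factory=list)
    p_value: float | None = None
    q_value: float | None = None
    retrieved: bool | None = None


def pairwise_distance(X: np.ndarray, metric: str = "cosine") -> np.ndarray:
    """Full symmetric pairwise distance matrix.

    cosine: 1 - cosine similarity, in [0, 2]; euclidean: L2 norm;
    pearson: 1 - Pearson correlation, in [0, 2]. Degenerate rows (zero norm
    for cosine, constant for pearson) raise instead of producing NaN.
    """
    X = np.asarray(X, dtype=np.float64)
    _check_rows(X, metric)
    scipy_metric = "correlation" if metric == "pearson" else metric
    D = cdist(X, X, metric=scipy_metric)
    if metric in ("cosine", "pearson"):
        np.fill_diagonal(D, 0.0)
    return D


def distance_to(query: np.ndarray, candidates: np.ndarray, metric: str = "cosine") -> np.ndarray:
    """Distances from one query row to each candidate row."""
    query = np.atleast_2d(np.asarray(query, dtype=np.float64))
    candidates = np.asarray(candidates, dtype=np.float64)
    _check_rows(query, metric)
    _check_rows(candidates, metric)
    scipy_metric = "correlation" if metric == "pearson" else metric
    return cdist(query, candidates, metric=scipy_metric)[0]


def _check_rows(X: np.ndarray, metric: str) -> None:
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {_METRICS}")
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    if metric == "cosine":
        norms = np.linalg.norm(X, axis=1)
        if np.any(norms == 0):
            bad = np.flatnonzero(norms == 0)[:5]
            raise ValueError(f"zero-norm rows under cosine distance: {bad.tolist()}")
    elif metric == "pearson":
        if np.any(X.std(axis=1) == 0):
            bad = np.flatnonzero(X.std(axis=1) == 0)[:5]
            raise ValueError(f"constant rows under pearson distance: {bad.tolist()}")


def rank_relevance(
    distances: np.ndarray,
    is_positive: np.ndarray,
    tie_break: str = "pessimistic",
    rng: np.random.Generator | None = None,
) -> RelevanceList:
    """Sort candidates by increasing distance and binarize.

    Ties at equal distance are broken pessimistically by default: negatives
    precede positives, so tied matches never inflate AP. ``tie_break="random"``
    shuffles tied blocks with ``rng`` for sensitivity analyses.
    """
    distances = np.asarray(distances, dtype=np.float64)
    is_positive = np.asarray(is_positive, dtype=bool)
    if distances.shape != is_positive.shape or distances.ndim != 1:
        raise ValueError("distances and is_positive must be equal-length 1-D arrays")
    if np.isnan(distances).any():
        bad = np.flatnonzero(np.isnan(distances))
        raise ValueError(f"NaN distance for candidate(s) {bad.tolist()}")
    n_pos = int(is_positive.sum())
    n_total = len(distances)
    if tie_break == "pessimistic":
        # stable lexsort: distance first, then relevance (0 before 1)
        order = np.lexsort((is_positive.astype(np.int8), distances))
    elif tie_break == "random":
        rng = np.random.default_rng() if rng is None else rng
        order = np.lexsort((rng.random(n_total), distances))
    else:
        raise ValueError(f"unknown tie_break {tie_break!r}")
    return RelevanceList(is_positive[order].astype(np.int8), n_pos, n_total)


def average_precision(rl: RelevanceList) -> float:
    """Non-interpolated AP of a binary relevance list, in (0, 1]."""
    return float(_ap_from_ranks(rl.ranks))


def _ap_from_ranks(ranks: np.ndarray) -> float:
    ranks = np.asarray(ranks)
    n_pos = int(ranks.sum())
    if n_pos == 0:
        raise ValueError("average precision undefined with zero positives")
    hits = np.flatnonzero(ranks) + 1  # 1-based positions of correct matches
    precision_at_hits = np.arange(1, n_pos + 1) / hits
    return float(precision_at_hits.mean())


def ap_from_hit_positions(positions: np.ndarray) -> np.ndarray:
    """Vectorized AP for many lists given sorted 1-based hit positions.

    ``positions`` has shape (n_lists, n_pos), each row strictly increasing.
    Used by the permutation null, where only the hit positions matter.
    """
    positions = np.asarray(positions, dtype=np.float64)
    n_pos = positions.shape[1]
    ranks_of_hits = np.arange(1, n_pos + 1)[None, :]
    return (ranks_of_hits / positions).mean(axis=1)


def precision_at_k(rl: RelevanceList, k: int) -> float:
    """Fraction of the top-k ranks holding correct matches (helper)."""
    if not 1 <= k <= rl.n_total:
        raise ValueError("k out of range")
    return float(rl.ranks[:k].sum() / k)


def mean_ap(aps: list) -> float:
    """Arithmetic mean of AP values over a query group."""
    if len(aps) == 0:
        raise ValueError("cannot average an empty AP list")
    values = [a.ap if isinstance(a, APResult) else float(a) for a in aps]
    return float(np.mean(values))
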