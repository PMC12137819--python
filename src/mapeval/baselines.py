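"""Comparator two-sample methods: mp-value, MMD test, k-means separation.

These are the established multivariate alternatives against which the
retrieval (mAP) approach is benchmarked. Each takes two groups of profiles
(perturbation replicates vs controls) and decides whether they differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist
from sklearn.cluster import KMeans

__all__ = ["TwoGroupResult", "mp_value", "mmd_test", "kmeans_separation"]


@dataclass
class TwoGroupResult:
    statistic: float
    p_value: float | None = None
    success: bool | None = None
    n_permutations: int | None = None
    seed: int | None = None
    purity: float | None = None
    bandwidth: float | None = None


def _as_groups(group_a, group_b):
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("groups must be 2-D with matching feature counts")
    return a, b


def _permutation_masks(rng, n_perm: int, n: int, n_a: int) -> np.ndarray:
    """0/1 matrix (n_perm, n): each row selects n_a pooled rows as group a."""
    keys = rng.random((n_perm, n))
    sel = np.argpartition(keys, n_a - 1, axis=1)[:, :n_a]
    Z = np.zeros((n_perm, n))
    np.put_along_axis(Z, sel, 1.0, axis=1)
    return Z


def mp_value(
    group_a,
    group_b,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> TwoGroupResult:
    """Multidimensional perturbation value: PCA + Mahalanobis + permutation.

    The pooled sample is projected onto its principal components; the
    scores of each component are weighted by its fraction of explained
    variance, and the Mahalanobis distance between the two group centroids
    is computed in this weighted space (pooled covariance with a small
    ridge for invertibility). Significance is the fraction of group-label
    permutations with a distance at least as large. Because label
    permutation leaves the pooled sample unchanged, the PCA of every
    permuted dataset coincides with the original projection, so the
    projection is computed once.
    """
    a, b = _as_groups(group_a, group_b)
    n_a, n_b = len(a), len(b)
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 rows")
    if n_a + n_b < 4:
        raise ValueError("need at least 4 profiles in total")
    X = np.vstack([a, b])
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    if s[0] <= 0:
        # all points identical: zero distance, permutations cannot beat it
        return TwoGroupResult(0.0, 1.0, n_permutations=n_permutations, seed=seed)
    keep = s > s[0] * 1e-12
    scores = U[:, keep] * s[keep]
    var_frac = s[keep] ** 2 / np.sum(s**2)
    W = scores * var_frac  # variance-explained weighting of PC scores
    k = W.shape[1]

    cov = np.cov(W, rowvar=False)
    cov = np.atleast_2d(cov)
    cov += np.eye(k) * (1e-6 * np.trace(cov) / k)
    cov_inv = np.linalg.inv(cov)

    def mahalanobis(diff):
        return np.sqrt(np.einsum("...i,ij,...j->...", diff, cov_inv, diff))

    observed = float(mahalanobis(W[:n_a].mean(axis=0) - W[n_a:].mean(axis=0)))

    rng = np.random.default_rng(seed)
    Z = _permutation_masks(rng, n_permutations, n_a + n_b, n_a)
    diffs = (Z @ W) / n_a - ((1.0 - Z) @ W) / n_b
    perm = mahalanobis(diffs)
    p = (1 + int((perm >= observed - 1e-12).sum())) / (1 + n_permutations)
    return TwoGroupResult(observed, p, n_permutations=n_permutations, seed=seed)


def mmd_test(
    group_a,
    group_b,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> TwoGroupResult:
    """Unbiased MMD^2 two-sample test with an RBF kernel.

    The kernel bandwidth sigma is the median pairwise Euclidean distance
    over the pooled sample (median heuristic); the kernel is
    exp(-d^2 / (2 sigma^2)). The unbiased estimator excludes diagonal
    terms. Significance by group-label permutation on the precomputed
    kernel matrix.
    """
    a, b = _as_groups(group_a, group_b)
    n_a, n_b = len(a), len(b)
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 rows")
    X = np.vstack([a, b])
    d = pdist(X)
    sigma = float(np.median(d))
    if sigma == 0:
        raise ValueError("median pairwise distance is zero (all points identical)")
    D2 = cdist(X, X, "sqeuclidean")
    K = np.exp(-D2 / (2.0 * sigma**2))

    def mmd2(z: np.ndarray) -> np.ndarray:
        # z: (m, n) 0/1 selection of group a; diagonals of K are 1
        KZ = z @ K
        s_a = (KZ * z).sum(axis=1)
        w = 1.0 - z
        s_b = ((w @ K) * w).sum(axis=1)
        s_ab = K.sum() - s_a - s_b
        return (
            (s_a - n_a) / (n_a * (n_a - 1))
            + (s_b - n_b) / (n_b * (n_b - 1))
            - s_ab / (n_a * n_b)
        )

    z_obs = np.zeros((1, n_a + n_b))
    z_obs[0, :n_a] = 1.0
    observed = float(mmd2(z_obs)[0])

    rng = np.random.default_rng(seed)
    Z = _permutation_masks(rng, n_permutations, n_a + n_b, n_a)
    perm = mmd2(Z)
    p = (1 + int((perm >= observed - 1e-12).sum())) / (1 + n_permutations)
    return TwoGroupResult(
        observed, p, n_permutations=n_permutations, seed=seed, bandwidth=sigma
    )


def kmeans_separation(
    group_a,
    group_b,
    n_restarts: int = 10,
    seed: int | None = None,
) -> TwoGroupResult:
    """2-means clustering of the pooled sample, judged against the groups.

    Centroids are initialized randomly; the lowest-inertia solution over
    ``n_restarts`` runs is kept. Success requires the cluster partition to
    equal the group partition exactly (up to label swap); ``purity``
    reports the softer agreement fraction.
    """
    a, b = _as_groups(group_a, group_b)
    X = np.vstack([a, b])
    if len(X) < 2:
        raise ValueError("need at least 2 profiles")
    truth = np.r_[np.zeros(len(a), dtype=int), np.ones(len(b), dtype=int)]
    km = KMeans(n_clusters=2, n_init=n_restarts, init="random", random_state=seed)
    labels = km.fit_predict(X)
    agree = max(np.mean(labels == truth), np.mean(labels == 1 - truth))
    return TwoGroupResult(
        float(km.inertia_),
        success=bool(agree == 1.0),
        seed=seed,
        purity=float(agree),
    )
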