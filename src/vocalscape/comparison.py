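"""Kernel two-sample comparison of vocal repertoires.

The maximum mean discrepancy (MMD) between two samples of latent vectors
is estimated with the biased V-statistic under a radial-basis kernel,

    MMD^2(X, Y) = mean k(X, X) + mean k(Y, Y) - 2 mean k(X, Y),

which is nonnegative and exactly zero for identical multisets.  The
kernel bandwidth defaults to the median heuristic (median pairwise
distance of the pooled sample), recomputed per comparison.  Significance
comes from a permutation test: the observed statistic is the mean MMD^2
over batches of randomly subsampled points, compared against the same
statistic under random relabelings, with an add-one p-value.

Also provides pairwise group distance matrices, classical (Torgerson)
multidimensional scaling, and PCA of daily usage vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.decomposition import PCA

_MAX_PRECOMPUTE = 12000      # pooled size up to which the kernel is cached
_BANDWIDTH_SUBSAMPLE = 2000  # points used for the median heuristic


@dataclass
class MMDResult:
    """Outcome of a batched MMD^2 permutation test."""

    mmd2: float
    null_values: np.ndarray
    p_value: float
    batch_size: int
    n_permutations: int
    bandwidth: float
    batch_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    small_sample: bool = False  # batch shrunk to the smaller sample size


@dataclass
class DistanceMatrix:
    """Symmetric group-by-group distance matrix with labels."""

    entries: np.ndarray
    groups: list
    flagged: np.ndarray | None = None  # True where a group had < 2 points

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, dtype=float)
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise ValueError("entries must be square")
        self.entries = e


def median_bandwidth(Z: np.ndarray, max_points: int = _BANDWIDTH_SUBSAMPLE,
                     seed: int = 0) -> float:
    """Median pairwise Euclidean distance (median heuristic).

    Subsamples at most ``max_points`` rows for tractability; falls back
    to 1.0 if the median distance is zero.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if len(Z) > max_points:
        rng = np.random.default_rng(seed)
        Z = Z[rng.choice(len(Z), max_points, replace=False)]
    if len(Z) < 2:
        return 1.0
    med = float(np.median(pdist(Z)))
    return med if med > 0 else 1.0


def _rbf(A: np.ndarray, B: np.ndarray, bandwidth: float) -> np.ndarray:
    d2 = cdist(A, B, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * bandwidth ** 2))


def mmd2(X: np.ndarray, Y: np.ndarray, bandwidth: float | None = None) -> float:
    """Biased (V-statistic) MMD^2 estimate with an RBF kernel."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.size == 0 or Y.size == 0:
        raise ValueError("both samples must be nonempty")
    if X.shape[1] != Y.shape[1]:
        raise ValueError("dimension mismatch")
    if bandwidth is None:
        bandwidth = median_bandwidth(np.vstack([X, Y]))
    val = (
        _rbf(X, X, bandwidth).mean()
        + _rbf(Y, Y, bandwidth).mean()
        - 2.0 * _rbf(X, Y, bandwidth).mean()
    )
    return float(max(val, 0.0))


def _batched_stat(K, x_idx, y_idx, batch, n_batches, rng):
    """Mean MMD^2 over batches, from a precomputed pooled kernel."""
    vals = np.empty(n_batches)
    for b in range(n_batches):
        bx = rng.choice(x_idx, size=batch, replace=False)
        by = rng.choice(y_idx, size=batch, replace=False)
        kxx = K[np.ix_(bx, bx)].mean()
        kyy = K[np.ix_(by, by)].mean()
        kxy = K[np.ix_(bx, by)].mean()
        vals[b] = max(kxx + kyy - 2.0 * kxy, 0.0)
    return vals


def mmd_permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    batch_size: int = 1000,
    n_permutations: int = 1000,
    seed: int = 0,
    bandwidth: float | None = None,
) -> MMDResult:
    """Batched MMD^2 permutation test between two latent samples.

    The observed statistic is the mean MMD^2 over
    ``floor(min(|X|,|Y|) / batch_size)`` (at least 1) batches of
    ``batch_size`` points subsampled from each side without replacement.
    The null is built by permuting the sample labels of the pooled data
    and recomputing the same batched statistic;
    ``p = (1 + #{null >= observed}) / (1 + n_permutations)``.

    When both samples are smaller than ``batch_size`` the batch shrinks
    to the smaller sample size and the result is flagged.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("dimension mismatch")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    nx, ny = len(X), len(Y)
    n_min = min(nx, ny)
    batch = min(batch_size, n_min)
    small = batch < batch_size
    n_batches = max(1, n_min // batch)
    pooled = np.vstack([X, Y])
    if bandwidth is None:
        bandwidth = median_bandwidth(pooled, seed=int(rng.integers(2 ** 31)))
    n_tot = nx + ny
    if n_tot <= _MAX_PRECOMPUTE:
        K = _rbf(pooled, pooled, bandwidth).astype(np.float32)
        x_idx = np.arange(nx)
        y_idx = np.arange(nx, n_tot)
        batch_vals = _batched_stat(K, x_idx, y_idx, batch, n_batches, rng)
        observed = float(batch_vals.mean())
        null = np.empty(n_permutations)
        for p in range(n_permutations):
            perm = rng.permutation(n_tot)
            null[p] = _batched_stat(
                K, perm[:nx], perm[nx:], batch, n_batches, rng
            ).mean()
    else:  # pooled kernel too large to cache; compute per batch
        def stat(A, B):
            vals = np.empty(n_batches)
            for b in range(n_batches):
                bx = rng.choice(len(A), size=batch, replace=False)
                by = rng.choice(len(B), size=batch, replace=False)
                vals[b] = mmd2(A[bx], B[by], bandwidth)
            return vals

        batch_vals = stat(X, Y)
        observed = float(batch_vals.mean())
        null = np.empty(n_permutations)
        for p in range(n_permutations):
            perm = rng.permutation(n_tot)
            null[p] = stat(pooled[perm[:nx]], pooled[perm[nx:]]).mean()
    p_value = (1.0 + np.sum(null >= observed)) / (1.0 + n_permutations)
    return MMDResult(
        mmd2=observed,
        null_values=null,
        p_value=float(p_value),
        batch_size=batch,
        n_permutations=n_permutations,
        bandwidth=float(bandwidth),
        batch_values=batch_vals,
        small_sample=small,
    )


def pairwise_group_mmd(groups: dict) -> DistanceMatrix:
    """All-pairs MMD^2 between labeled groups of latent vectors.

    ``groups`` maps a hashable label — e.g. ``(cohort, day)`` — to an
    ``(n_g, D)`` array.  Entries involving a group with fewer than 2
    points are NaN and flagged.  The bandwidth is recomputed per pair by
    the median heuristic.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.atleast_2d(np.asarray(groups[g], dtype=float)) for g in labels]
    m = len(labels)
    D = np.zeros((m, m))
    flagged = np.zeros(m, dtype=bool)
    for i, a in enumerate(arrays):
        if len(a) < 2:
            flagged[i] = True
    for i in range(m):
        for j in range(i + 1, m):
            if flagged[i] or flagged[j]:
                D[i, j] = D[j, i] = np.nan
            else:
                D[i, j] = D[j, i] = mmd2(arrays[i], arrays[j])
    return DistanceMatrix(D, labels, flagged)


def mds_embed(distances: DistanceMatrix | np.ndarray, dim: int = 2) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling of a distance matrix.

    Double-centers the squared distances and embeds on the top ``dim``
    nonnegative eigenvalues; exact for Euclidean-realizable inputs (up
    to rigid motion).
    """
    D = distances.entries if isinstance(distances, DistanceMatrix) else np.asarray(
        distances, dtype=float
    )
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10, equal_nan=True):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < -1e-12):
        raise ValueError("distances must be nonnegative")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:dim]
    w = np.maximum(w[order], 0.0)
    return V[:, order] * np.sqrt(w)


@dataclass
class UsagePCA:
    coordinates: np.ndarray
    explained_variance_ratio: np.ndarray
    zero_variance: bool = False


def daily_usage_pca(usage: np.ndarray, n_components: int = 2) -> UsagePCA:
    """PCA of (cohort-day) x cluster usage rows.

    Rows are centered; returns projections onto the top components and
    their explained-variance fractions.  A constant matrix is flagged
    and projects to the origin.
    """
    usage = np.atleast_2d(np.asarray(usage, dtype=float))
    if len(usage) < 2:
        raise ValueError("need at least 2 rows")
    if np.allclose(usage.var(axis=0), 0.0):
        k = min(n_components, usage.shape[1])
        return UsagePCA(np.zeros((len(usage), k)), np.zeros(k), zero_variance=True)
    k = min(n_components, len(usage) - 1, usage.shape[1])
    pca = PCA(n_components=k)
    coords = pca.fit_transform(usage)
    return UsagePCA(coords, pca.explained_variance_ratio_)
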