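"""Hierarchical Gaussian mixture with cohort-specific cluster usage.

The generative model for latent vector ``x_ik`` (vocalization ``k`` of
cohort ``i``), with ``K`` clusters in ``D`` dimensions:

    beta_j   ~ Normal_D(0, mean_prior_sd)          cluster means
    sigma_j  ~ Half-Normal_D(scale_prior_sd)       cluster scales
    theta_i  ~ Dirichlet(1, ..., 1)                usage per cohort
    z_ik     ~ Categorical(theta_i)
    x_ik     ~ Normal(beta_{z_ik}, diag(sigma_{z_ik})^2)

Unlike a pooled mixture, each cohort carries its own usage simplex
``theta_i`` over a shared set of components — the model is free, but not
forced, to learn different usage patterns per cohort.

Two fitting routes share the same E-step machinery:

``em_map``
    Expectation-maximization on the MAP objective.  Every M-step update
    is closed-form, including the half-normal scale prior (its
    stationarity condition is a quadratic in sigma^2).

``variational``
    Structured variational EM: ``q(z)`` categorical and ``q(theta_i)``
    Dirichlet updated in closed form, with ``(beta, sigma)``
    point-estimated at their MAP.  Responsibilities use
    ``E[log theta]`` under the Dirichlet posterior.

Both return point parameters (``theta_i`` is the Dirichlet posterior
mean under ``variational``), per-point responsibilities, and hard
assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import digamma, logsumexp
from sklearn.cluster import KMeans

from .embedding import LatentDataset

_SIGMA_FLOOR = 1e-3


@dataclass
class PriorSpec:
    """Weakly informative priors for the cohort mixture."""

    mean_prior_sd: float = 5.0
    scale_prior_sd: float = 3.0
    usage_concentration: float = 1.0

    def __post_init__(self) -> None:
        if min(self.mean_prior_sd, self.scale_prior_sd, self.usage_concentration) <= 0:
            raise ValueError("all prior hyperparameters must be positive")


@dataclass
class CohortGMMParams:
    """Fitted cohort-mixture parameters plus responsibilities."""

    K: int
    D: int
    means: np.ndarray              # (K, D) beta_j
    scales: np.ndarray             # (K, D) sigma_j > 0
    usages: np.ndarray             # (n_cohorts, K) theta_i, rows on the simplex
    assignments: np.ndarray        # (n,) argmax responsibility, in {0..K-1}
    responsibilities: np.ndarray   # (n, K), rows sum to 1
    objective: float = float("nan")
    objective_history: list[float] = field(default_factory=list)
    method: str = "em_map"

    def __post_init__(self) -> None:
        if np.any(self.scales <= 0):
            raise ValueError("scales must be positive")
        if not np.allclose(self.usages.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("usage rows must sum to 1")

    @property
    def n_cohorts(self) -> int:
        return self.usages.shape[0]


def _log_gauss(X: np.ndarray, means: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """(n, K) log density of diagonal normals."""
    var = scales ** 2
    const = -0.5 * np.sum(np.log(2 * np.pi * var), axis=1)  # (K,)
    # (n, K) quadratic term
    quad = (
        (X ** 2) @ (0.5 / var).T
        - X @ (means / var).T
        + 0.5 * np.sum(means ** 2 / var, axis=1)
    )
    return const - quad


def _map_objective(
    X, cohorts, means, scales, usages, priors: PriorSpec
) -> float:
    """Observed-data log posterior at point parameters (up to constants)."""
    log_th = np.log(np.maximum(usages, 1e-300))
    ll = float(np.sum(logsumexp(log_th[cohorts] + _log_gauss(X, means, scales), axis=1)))
    lp = -0.5 * np.sum(means ** 2) / priors.mean_prior_sd ** 2
    lp += -0.5 * np.sum(scales ** 2) / priors.scale_prior_sd ** 2
    lp += (priors.usage_concentration - 1.0) * np.sum(np.log(np.maximum(usages, 1e-300)))
    return ll + lp


def _m_step_gauss(X, R, means, scales, priors: PriorSpec):
    """Closed-form MAP updates for means then scales given responsibilities."""
    Nk = R.sum(axis=0)  # (K,)
    S1 = R.T @ X        # (K, D)
    var = scales ** 2
    means = S1 / (Nk[:, None] + var / priors.mean_prior_sd ** 2)
    # scales: d/dsigma [ -N log sigma - S/(2 sigma^2)... ] with half-normal prior
    # stationarity: sigma^4 / s^2 + N sigma^2 - S = 0  (per dimension)
    S2 = R.T @ (X ** 2) - 2 * means * S1 + (means ** 2) * Nk[:, None]
    S2 = np.maximum(S2, 0.0)
    s2 = priors.scale_prior_sd ** 2
    u = 0.5 * s2 * (-Nk[:, None] + np.sqrt(Nk[:, None] ** 2 + 4 * S2 / s2))
    scales = np.sqrt(np.maximum(u, _SIGMA_FLOOR ** 2))
    return means, scales


def _init(X, cohorts, K, n_cohorts, priors, rng):
    km = KMeans(n_clusters=K, n_init=1, random_state=int(rng.integers(2 ** 31)))
    labels = km.fit_predict(X)
    means = km.cluster_centers_.copy()
    scales = np.ones((K, X.shape[1]))
    for k in range(K):
        pts = X[labels == k]
        if len(pts) > 1:
            scales[k] = np.maximum(pts.std(axis=0), 0.05)
    usages = np.full((n_cohorts, K), 1.0)
    for i in range(n_cohorts):
        sel = labels[cohorts == i]
        usages[i] += np.bincount(sel, minlength=K)
    usages /= usages.sum(axis=1, keepdims=True)
    return means, scales, usages


def fit(
    latents: LatentDataset,
    K: int,
    priors: PriorSpec | None = None,
    seed: int = 0,
    method: str = "variational",
    restarts: int = 5,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> CohortGMMParams:
    """Fit the cohort mixture; keeps the best of ``restarts`` initializations."""
    priors = priors or PriorSpec()
    X = latents.z
    cohorts = latents.cohort_ids
    n, D = X.shape
    if K < 1 or K > n:
        raise ValueError(f"need 1 <= K <= n, got K={K}, n={n}")
    if not np.all(np.isfinite(X)):
        raise ValueError("latents must be finite")
    if method not in ("variational", "em_map"):
        raise ValueError(f"unknown method {method!r}")
    n_cohorts = latents.n_cohorts
    best: CohortGMMParams | None = None
    rng = np.random.default_rng(seed)
    for _ in range(max(1, restarts)):
        params = _fit_once(
            X, cohorts, K, n_cohorts, priors, rng, method, max_iter, tol
        )
        if best is None or params.objective > best.objective:
            best = params
    return best


def _fit_once(X, cohorts, K, n_cohorts, priors, rng, method, max_iter, tol):
    n, D = X.shape
    means, scales, usages = _init(X, cohorts, K, n_cohorts, priors, rng)
    alpha0 = priors.usage_concentration
    cohort_masks = [cohorts == i for i in range(n_cohorts)]
    n_i = np.array([m.sum() for m in cohort_masks])
    history: list[float] = []
    prev = -np.inf
    R = None
    for _ in range(max_iter):
        # E-step
        if method == "variational":
            # E[log theta] under the Dirichlet posterior from the previous R
            if R is None:
                e_log_th = np.log(np.maximum(usages, 1e-300))
            else:
                alpha = np.full((n_cohorts, K), alpha0)
                for i, m in enumerate(cohort_masks):
                    alpha[i] += R[m].sum(axis=0)
                e_log_th = digamma(alpha) - digamma(alpha.sum(axis=1, keepdims=True))
        else:
            e_log_th = np.log(np.maximum(usages, 1e-300))
        logR = e_log_th[cohorts] + _log_gauss(X, means, scales)
        logR -= logsumexp(logR, axis=1, keepdims=True)
        R = np.exp(logR)
        # M-step
        means, scales = _m_step_gauss(X, R, means, scales, priors)
        if method == "variational":
            alpha = np.full((n_cohorts, K), alpha0)
            for i, m in enumerate(cohort_masks):
                alpha[i] += R[m].sum(axis=0)
            usages = alpha / alpha.sum(axis=1, keepdims=True)
        else:
            for i, m in enumerate(cohort_masks):
                num = R[m].sum(axis=0) + (alpha0 - 1.0)
                den = n_i[i] + K * (alpha0 - 1.0)
                u = np.maximum(num, 1e-12) / max(den, 1e-12)
                usages[i] = u / u.sum()
        obj = _map_objective(X, cohorts, means, scales, usages, priors)
        history.append(obj)
        if obj - prev < tol * max(1.0, abs(prev)) and len(history) > 1:
            break
        prev = obj
    return CohortGMMParams(
        K=K,
        D=D,
        means=means,
        scales=scales,
        usages=usages,
        assignments=np.argmax(R, axis=1),
        responsibilities=R,
        objective=history[-1],
        objective_history=history,
        method=method,
    )


def heldout_loglik(model: CohortGMMParams, latents: LatentDataset) -> float:
    """Total log marginal likelihood of held-out points under the model.

    For each point, ``log sum_j theta_{i,j} N(x | beta_j, Sigma_j)`` with
    ``i`` the point's cohort.  Empty input returns 0.
    """
    if len(latents) == 0:
        return 0.0
    if latents.cohort_ids.max() >= model.n_cohorts or latents.cohort_ids.min() < 0:
        raise ValueError("held-out cohort id unknown to the model")
    log_th = np.log(np.maximum(model.usages, 1e-300))
    lp = logsumexp(
        log_th[latents.cohort_ids] + _log_gauss(latents.z, model.means, model.scales),
        axis=1,
    )
    return float(lp.sum())


@dataclass
class KSelection:
    """Held-out likelihood curve over a K grid and the knee choice."""

    K_grid: np.ndarray
    heldout: np.ndarray
    chosen_K: int


def select_K(
    latents: LatentDataset,
    K_grid,
    holdout_fraction: float = 0.25,
    seed: int = 0,
    method: str = "em_map",
    restarts: int = 2,
    max_iter: int = 100,
) -> KSelection:
    """Hold out a fraction of the data and pick K at the likelihood knee.

    The knee is the interior grid point with the most negative discrete
    second difference of the held-out log-likelihood curve (maximum
    curvature of an increasing, saturating curve).  Grids with fewer
    than 3 points fall back to the argmax of held-out likelihood.  The
    full curve is returned so the choice can be overridden.
    """
    K_grid = np.asarray(sorted(K_grid), dtype=int)
    if K_grid.size == 0:
        raise ValueError("empty K grid")
    n = len(latents)
    n_hold = int(round(holdout_fraction * n))
    if n_hold >= n:
        raise ValueError("holdout larger than dataset")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    hold_mask = np.zeros(n, dtype=bool)
    hold_mask[perm[:n_hold]] = True
    train = latents.subset(~hold_mask)
    hold = latents.subset(hold_mask)
    curve = np.empty(len(K_grid))
    for idx, K in enumerate(K_grid):
        model = fit(
            train,
            int(K),
            seed=int(rng.integers(2 ** 31)),
            method=method,
            restarts=restarts,
            max_iter=max_iter,
        )
        curve[idx] = heldout_loglik(model, hold)
    if len(K_grid) < 3:
        chosen = int(K_grid[np.argmax(curve)])
    else:
        d2 = curve[:-2] - 2 * curve[1:-1] + curve[2:]
        chosen = int(K_grid[1 + int(np.argmin(d2))])
    return KSelection(K_grid, curve, chosen)


def cluster_usage(
    assignments: np.ndarray, cohorts: np.ndarray, K: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Empirical cohort-by-cluster usage proportions.

    Returns ``(usage, order, empty_cohorts)``: ``usage[i]`` is the
    empirical distribution of assignments over cohort ``i`` (NaN rows for
    empty cohorts, flagged in ``empty_cohorts``); ``order`` sorts
    clusters by decreasing maximum cross-cohort usage difference.
    """
    assignments = np.asarray(assignments, dtype=int)
    cohorts = np.asarray(cohorts, dtype=int)
    if K is None:
        K = int(assignments.max()) + 1
    n_cohorts = int(cohorts.max()) + 1
    usage = np.full((n_cohorts, K), np.nan)
    empty = np.zeros(n_cohorts, dtype=bool)
    for i in range(n_cohorts):
        sel = assignments[cohorts == i]
        if sel.size == 0:
            empty[i] = True
            continue
        usage[i] = np.bincount(sel, minlength=K) / sel.size
    valid = usage[~empty]
    if len(valid) >= 2:
        diff = valid.max(axis=0) - valid.min(axis=0)
    else:
        diff = np.zeros(K)
    order = np.argsort(diff)[::-1]
    return usage, order, empty


def match_components(
    est_means: np.ndarray, true_means: np.ndarray
) -> np.ndarray:
    """Hungarian matching of estimated to true components by mean distance.

    Returns ``perm`` such that ``est_means[perm[j]]`` corresponds to
    ``true_means[j]``.
    """
    cost = np.linalg.norm(
        est_means[None, :, :] - true_means[:, None, :], axis=2
    )
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(len(true_means), dtype=int)
    perm[rows] = cols
    return perm
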