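"""Canned study designs built from the synthetic generator.

These functions wire the generator to the statistical machinery at the
scale used for validation: a two-family latent-space discrimination
study (distinct usage simplexes over a shared component set, compared
with the batched MMD^2 permutation test) and a parameter-recovery
design for the cohort mixture.
"""

from __future__ import annotations

import numpy as np

from . import comparison, mixture, synthetic
from .embedding import LatentDataset


def two_family_latents(
    seed: int = 0,
    n_per_family: int = 5000,
    K: int = 10,
    D: int = 7,
    separation: float = 3.0,
    usage_tv: float = 0.4,
) -> tuple[LatentDataset, LatentDataset]:
    """Latent samples for two families with usage simplexes ``usage_tv`` apart.

    Component means are drawn once (from ``seed``) with expected
    pairwise distance ``separation`` and unit scales; family 1 uses the
    uniform simplex, family 2 shifts mass so the total-variation
    distance between the simplexes is exactly ``usage_tv``.
    """
    if not 0 <= usage_tv <= 1 or K % 2:
        raise ValueError("need usage_tv in [0,1] and even K")
    rng = np.random.default_rng(seed)
    # E||m_a - m_b|| ~ sd * sqrt(2 D) for iid normal coordinates
    means = rng.standard_normal((K, D)) * (separation / np.sqrt(2 * D))
    scales = np.ones_like(means)
    usage_a = np.full(K, 1.0 / K)
    shift = 2.0 * usage_tv / K
    usage_b = usage_a + np.where(np.arange(K) < K // 2, shift, -shift)
    fam_a = synthetic.sample_latents(
        usage_a, means, scales, n_per_family, cohort_id=0,
        seed=int(rng.integers(2 ** 31)),
    )
    fam_b = synthetic.sample_latents(
        usage_b, means, scales, n_per_family, cohort_id=1,
        seed=int(rng.integers(2 ** 31)),
    )
    return fam_a, fam_b


def family_discrimination_test(
    seed: int = 0,
    n_per_family: int = 5000,
    batch_size: int = 1000,
    n_permutations: int = 1000,
    **design,
) -> comparison.MMDResult:
    """Run the MMD^2 permutation test on the two-family latent design."""
    fam_a, fam_b = two_family_latents(seed, n_per_family, **design)
    return comparison.mmd_permutation_test(
        fam_a.z,
        fam_b.z,
        batch_size=batch_size,
        n_permutations=n_permutations,
        seed=seed,
    )


def usage_recovery_design(
    seed: int = 0, n_per_cohort: int = 2000
) -> tuple[LatentDataset, np.ndarray, np.ndarray]:
    """Three cohorts over three well-separated components (D=2).

    Returns ``(latents, true_means, true_usages)`` for scoring recovery
    of the cohort mixture fit.
    """
    rng = np.random.default_rng(seed)
    means = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 5.0]])
    thetas = np.array(
        [[0.7, 0.2, 0.1], [0.1, 0.7, 0.2], [0.2, 0.1, 0.7]]
    )
    zs, cs = [], []
    for i, theta in enumerate(thetas):
        lab = rng.choice(3, n_per_cohort, p=theta)
        zs.append(means[lab] + rng.standard_normal((n_per_cohort, 2)))
        cs.append(np.full(n_per_cohort, i))
    return (
        LatentDataset(np.vstack(zs), np.concatenate(cs)),
        means,
        thetas,
    )


def score_usage_recovery(
    seed: int = 0, n_per_cohort: int = 2000, restarts: int = 3
) -> dict[str, float]:
    """Fit the cohort mixture on the recovery design and score errors."""
    latents, means, thetas = usage_recovery_design(seed, n_per_cohort)
    model = mixture.fit(latents, K=3, seed=seed, restarts=restarts)
    perm = mixture.match_components(model.means, means)
    return {
        "usage_max_error": float(np.abs(model.usages[:, perm] - thetas).max()),
        "mean_max_error": float(np.abs(model.means[perm] - means).max()),
    }


def knee_selection_design(seed: int = 0, n: int = 1500) -> mixture.KSelection:
    """Held-out K selection on three equidistant components (true K = 3)."""
    rng = np.random.default_rng(seed)
    means = np.array([[0.0, 0.0], [10.0, 0.0], [5.0, 8.66]])
    lab = rng.choice(3, n)
    z = means[lab] + rng.standard_normal((n, 2))
    latents = LatentDataset(z, np.zeros(n, int))
    return mixture.select_K(
        latents, range(1, 9), seed=seed, restarts=2, max_iter=100
    )
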