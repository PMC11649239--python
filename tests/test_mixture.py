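"""Cohort mixture model: fitting, held-out likelihood, K selection, usage."""

import numpy as np
import pytest

from vocalscape import mixture
from vocalscape.embedding import LatentDataset


def _simulate(means, thetas, n_per_cohort, scales=None, seed=0):
    """Draw latents from the generative model; returns dataset + labels."""
    rng = np.random.default_rng(seed)
    means = np.asarray(means, float)
    if scales is None:
        scales = np.ones_like(means)
    zs, cs, labs = [], [], []
    for i, theta in enumerate(np.atleast_2d(thetas)):
        lab = rng.choice(len(means), n_per_cohort, p=theta)
        zs.append(means[lab] + scales[lab] * rng.standard_normal((n_per_cohort, means.shape[1])))
        cs.append(np.full(n_per_cohort, i))
        labs.append(lab)
    return (
        LatentDataset(np.vstack(zs), np.concatenate(cs)),
        np.concatenate(labs),
    )


class TestFit:
    def test_single_component_moment_oracle(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal((1000, 2)) + 3.0
        lat = LatentDataset(z, np.zeros(1000, int))
        m = mixture.fit(lat, 1, seed=0, restarts=1)
        # prior shrinkage is negligible at n=1000
        assert np.abs(m.means[0] - z.mean(axis=0)).max() < 0.05
        assert np.abs(m.means[0] - 3.0).max() < 0.1
        assert np.abs(m.scales[0] - 1.0).max() < 0.1

    @pytest.mark.parametrize("method", ["variational", "em_map"])
    def test_two_cohort_usage_recovery(self, method):
        means = [[-5.0, 0.0], [5.0, 0.0]]
        thetas = [[0.9, 0.1], [0.1, 0.9]]
        lat, _ = _simulate(means, thetas, 2000, seed=1)
        m = mixture.fit(lat, 2, seed=1, method=method, restarts=3)
        perm = mixture.match_components(m.means, np.asarray(means))
        assert np.abs(m.usages[:, perm] - thetas).max() < 0.05

    def test_three_cohort_parameter_recovery(self):
        means = [[0.0, 0.0], [5.0, 0.0], [0.0, 5.0]]
        thetas = [[0.7, 0.2, 0.1], [0.1, 0.7, 0.2], [0.2, 0.1, 0.7]]
        lat, _ = _simulate(means, thetas, 2000, seed=2)
        m = mixture.fit(lat, 3, seed=2, restarts=3)
        perm = mixture.match_components(m.means, np.asarray(means))
        assert np.abs(m.usages[:, perm] - thetas).max() <= 0.05
        assert np.abs(m.means[perm] - means).max() <= 0.2

    def test_usages_on_simplex_and_responsibilities_normalized(self):
        lat, _ = _simulate([[0.0], [4.0]], [[0.5, 0.5]], 300, seed=3)
        m = mixture.fit(lat, 2, seed=0, restarts=1)
        assert np.allclose(m.usages.sum(axis=1), 1.0, atol=1e-8)
        assert np.all(m.usages >= 0)
        assert np.allclose(m.responsibilities.sum(axis=1), 1.0)
        assert np.array_equal(m.assignments, m.responsibilities.argmax(axis=1))

    def test_em_map_objective_nondecreasing(self):
        lat, _ = _simulate([[0.0, 0.0], [4.0, 4.0]], [[0.6, 0.4]], 500, seed=4)
        m = mixture.fit(lat, 2, seed=0, method="em_map", restarts=1)
        h = np.asarray(m.objective_history)
        assert np.all(np.diff(h) >= -1e-6 * np.maximum(1.0, np.abs(h[:-1])))

    def test_invalid_K_rejected(self):
        lat, _ = _simulate([[0.0]], [[1.0]], 5, seed=0)
        with pytest.raises(ValueError):
            mixture.fit(lat, 10)

    def test_agrees_with_pooled_reference_mixture(self):
        # uniform cohort pooling reduces to a standard diagonal GMM;
        # sklearn is the independent reference implementation
        from sklearn.mixture import GaussianMixture

        lat, _ = _simulate(
            [[-6.0, 0.0], [6.0, 0.0]], [[0.5, 0.5]], 1000, seed=5
        )
        m = mixture.fit(lat, 2, seed=0, method="em_map", restarts=3)
        ref = GaussianMixture(
            2, covariance_type="diag", random_state=0, n_init=3
        ).fit_predict(lat.z)
        agree = max(
            np.mean(m.assignments == ref), np.mean(m.assignments != ref)
        )
        assert agree >= 0.98


class TestHeldoutLoglik:
    def _model(self):
        means = np.array([[0.0, 0.0], [5.0, 5.0]])
        return mixture.CohortGMMParams(
            K=2, D=2, means=means, scales=np.full((2, 2), 0.5),
            usages=np.array([[0.5, 0.5]]),
            assignments=np.zeros(1, int),
            responsibilities=np.ones((1, 2)) * 0.5,
        )

    def test_empty_heldout_is_zero(self):
        m = self._model()
        empty = LatentDataset(np.empty((0, 2)), np.empty(0, int))
        assert mixture.heldout_loglik(m, empty) == 0.0

    def test_monotone_in_distance_from_component(self):
        m = self._model()
        near = LatentDataset(np.array([[0.0, 0.0]]), [0])
        far = LatentDataset(np.array([[0.0, 10.0]]), [0])
        assert mixture.heldout_loglik(m, near) > mixture.heldout_loglik(m, far)

    def test_generating_model_beats_shifted_model(self):
        lat, _ = _simulate([[0.0, 0.0], [4.0, 0.0]], [[0.5, 0.5]], 200, seed=6)
        m_true = self._replace_means(np.array([[0.0, 0.0], [4.0, 0.0]]))
        m_shift = self._replace_means(np.array([[2.0, 2.0], [6.0, 2.0]]))
        assert mixture.heldout_loglik(m_true, lat) > mixture.heldout_loglik(
            m_shift, lat
        )

    def _replace_means(self, means):
        return mixture.CohortGMMParams(
            K=2, D=2, means=means, scales=np.ones((2, 2)),
            usages=np.array([[0.5, 0.5]]),
            assignments=np.zeros(1, int),
            responsibilities=np.ones((1, 2)) * 0.5,
        )

    def test_invariant_to_cluster_relabeling(self):
        lat, _ = _simulate([[0.0, 0.0], [4.0, 0.0]], [[0.3, 0.7]], 100, seed=7)
        means = np.array([[0.0, 0.0], [4.0, 0.0]])
        m = self._replace_means(means)
        m.usages = np.array([[0.3, 0.7]])
        swapped = mixture.CohortGMMParams(
            K=2, D=2, means=means[::-1].copy(), scales=np.ones((2, 2)),
            usages=np.array([[0.7, 0.3]]),
            assignments=np.zeros(1, int),
            responsibilities=np.ones((1, 2)) * 0.5,
        )
        a = mixture.heldout_loglik(m, lat)
        b = mixture.heldout_loglik(swapped, lat)
        assert a == pytest.approx(b, rel=1e-12)

    def test_unknown_cohort_rejected(self):
        m = self._model()
        lat = LatentDataset(np.zeros((1, 2)), [4])
        with pytest.raises(ValueError):
            mixture.heldout_loglik(m, lat)


class TestSelectK:
    def test_singleton_grid(self):
        lat, _ = _simulate([[0.0], [4.0]], [[0.5, 0.5]], 200, seed=0)
        sel = mixture.select_K(lat, [5], seed=0)
        assert sel.chosen_K == 5

    def test_knee_at_true_cluster_count(self):
        means = [[0.0, 0.0], [10.0, 0.0], [5.0, 8.66]]
        lat, _ = _simulate(means, [[1 / 3, 1 / 3, 1 / 3]], 1500, seed=1)
        sel = mixture.select_K(
            lat, range(1, 9), seed=1, restarts=2, max_iter=100
        )
        assert sel.chosen_K == 3

    def test_default_holdout_fraction(self):
        import inspect

        sig = inspect.signature(mixture.select_K)
        assert sig.parameters["holdout_fraction"].default == 0.25

    def test_oversized_holdout_rejected(self):
        lat, _ = _simulate([[0.0]], [[1.0]], 10, seed=0)
        with pytest.raises(ValueError):
            mixture.select_K(lat, [1], holdout_fraction=1.0)


class TestClusterUsage:
    def test_one_hot_row(self):
        usage, _, empty = mixture.cluster_usage(
            np.full(10, 3), np.zeros(10, int), K=5
        )
        assert np.array_equal(usage[0], [0, 0, 0, 1, 0]) and not empty.any()

    def test_even_split(self):
        usage, _, _ = mixture.cluster_usage(
            np.array([0, 0, 1, 1]), np.zeros(4, int), K=2
        )
        assert np.array_equal(usage[0], [0.5, 0.5])

    def test_binomial_confidence_bands(self):
        theta = np.array([0.7, 0.2, 0.1])
        rng = np.random.default_rng(2)
        z = rng.choice(3, 5000, p=theta)
        usage, _, _ = mixture.cluster_usage(z, np.zeros(5000, int), K=3)
        sd = np.sqrt(theta * (1 - theta) / 5000)
        assert np.all(np.abs(usage[0] - theta) < 3 * sd + 1e-12)

    def test_empty_cohort_flagged(self):
        usage, _, empty = mixture.cluster_usage(
            np.array([0, 1]), np.array([0, 0]), K=2
        )
        # cohort ids are contiguous; build a 3-cohort case with a gap
        usage, _, empty = mixture.cluster_usage(
            np.array([0, 1]), np.array([0, 2]), K=2
        )
        assert empty[1] and not empty[0] and np.isnan(usage[1]).all()

    def test_difference_ordering(self):
        usage = np.array([[0.8, 0.1, 0.1], [0.1, 0.8, 0.1]])
        z = np.concatenate([
            np.random.default_rng(0).choice(3, 1000, p=usage[0]),
            np.random.default_rng(1).choice(3, 1000, p=usage[1]),
        ])
        cohorts = np.repeat([0, 1], 1000)
        _, order, _ = mixture.cluster_usage(z, cohorts, K=3)
        assert set(order[:2]) == {0, 1}  # the two differing clusters lead
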