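"""Generator correctness: repertoires, emission structure, rendering, latents."""

import numpy as np
import pytest

from vocalscape import synthetic as syn
from vocalscape.params import ParameterError


def _uniform_spec(K, **kw):
    return syn.FamilySpec(
        family_id=0,
        usage=np.full(K, 1.0 / K),
        transition=np.full((K, K), 1.0 / K),
        diurnal_rate=np.full(24, kw.pop("rate", 300.0)),
        **kw,
    )


class TestMakeRepertoire:
    def test_deterministic_per_seed(self):
        a = syn.make_repertoire(1, seed=0)
        b = syn.make_repertoire(1, seed=0)
        assert a == b and len(a) == 1

    def test_durations_within_syllable_bounds(self):
        tpls = syn.make_repertoire(10, seed=1)
        assert len(tpls) == 10
        assert all(0.03 <= t.duration <= 0.3 for t in tpls)
        assert all(500 <= t.f_start <= 62500 for t in tpls)

    def test_seeds_differ(self):
        a = syn.make_repertoire(10, seed=1)
        b = syn.make_repertoire(10, seed=2)
        assert a != b

    def test_templates_pairwise_distinct(self):
        tpls = syn.make_repertoire(20, seed=3)
        triples = {(t.f_start, t.f_end, t.duration) for t in tpls}
        assert len(triples) == 20

    def test_invalid_K(self):
        with pytest.raises(ParameterError):
            syn.make_repertoire(0)


class TestSimulateFamily:
    def test_degenerate_one_hot_usage(self, clean_templates):
        usage = np.zeros(4)
        usage[3] = 1.0
        spec = syn.FamilySpec(0, usage, np.eye(4), np.full(24, 300.0))
        truth = syn.simulate_family(spec, clean_templates, 0.2, seed=0)
        labels = truth.labels[truth.is_vocal]
        assert len(labels) > 50 and np.all(labels == 3)

    def test_empirical_usage_binomial_ci(self, clean_templates):
        spec = syn.FamilySpec(
            0,
            np.array([0.5, 0.5]),
            np.full((2, 2), 0.5),
            np.full(24, 2000.0),
        )
        truth = syn.simulate_family(spec, clean_templates, 2.5, seed=1)
        labels = truth.labels[truth.is_vocal]
        n = len(labels)
        assert n > 4000
        freq = np.mean(labels == 0)
        assert abs(freq - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_self_transition_recovery(self, clean_templates):
        K = 3
        trans = 0.8 * np.eye(K) + 0.1 * (1 - np.eye(K))
        spec = syn.FamilySpec(
            0, np.full(K, 1 / 3), trans, np.full(24, 2000.0)
        )
        truth = syn.simulate_family(spec, clean_templates, 2.5, seed=2)
        labels = truth.labels[truth.is_vocal]
        self_frac = np.mean(labels[:-1] == labels[1:])
        assert abs(self_frac - 0.8) < 0.03

    def test_transition_row_l1_recovery(self, clean_templates):
        spec = _uniform_spec(3, rate=2000.0)
        truth = syn.simulate_family(spec, clean_templates, 2.5, seed=3)
        labels = truth.labels[truth.is_vocal]
        counts = np.zeros((3, 3))
        np.add.at(counts, (labels[:-1], labels[1:]), 1)
        p = counts / counts.sum(axis=1, keepdims=True)
        assert np.abs(p - spec.transition).sum(axis=1).max() < 0.1

    def test_bout_structure_by_construction(self, clean_templates):
        from vocalscape.segmentation import SoundEvent
        from vocalscape.temporal import extract_bouts

        spec = _uniform_spec(4, rate=600.0)
        truth = syn.simulate_family(spec, clean_templates, 1.0, seed=4)
        events = [
            SoundEvent(a, b) for a, b, _, v in truth.events if v
        ]
        bouts, frac = extract_bouts(events)
        assert frac > 0.8  # only hour-trimmed remainder bouts fall short
        for bout in bouts:
            gaps = np.diff([e.onset for e in bout.member_events])
            assert np.all(gaps < 2.0) and bout.size >= 5

    def test_nonstochastic_transition_rejected(self):
        with pytest.raises(ParameterError):
            syn.FamilySpec(
                0, np.array([0.5, 0.5]), np.array([[0.5, 0.4], [0.5, 0.5]]),
                np.full(24, 10.0),
            )

    def test_seed_determinism(self, clean_templates):
        spec = _uniform_spec(4)
        a = syn.simulate_family(spec, clean_templates, 0.3, seed=9)
        b = syn.simulate_family(spec, clean_templates, 0.3, seed=9)
        assert a.events == b.events

    def test_events_sorted(self, clean_templates):
        spec = _uniform_spec(4, noise_event_rate=200.0)
        truth = syn.simulate_family(spec, clean_templates, 0.3, seed=5)
        onsets = truth.onsets
        assert np.all(np.diff(onsets) >= 0)


class TestRenderAudio:
    def test_empty_events_zero_floor(self, clean_templates):
        spec = _uniform_spec(4)
        truth = syn.FamilySimulationTruth([], spec, 0)
        wave = syn.render_audio(truth, clean_templates, duration=0.5)
        assert wave.shape == (62500,) and np.all(wave == 0.0)

    def test_energy_localized_to_event(self, clean_templates):
        tpl = clean_templates[0]  # duration 0.04
        spec = _uniform_spec(4)
        truth = syn.FamilySimulationTruth([(1.0, 1.0 + tpl.duration, 0, True)], spec, 0)
        wave = syn.render_audio(truth, clean_templates, duration=2.0)
        sr = 125000
        assert np.all(wave[: int(0.99 * sr)] == 0.0)
        assert np.all(wave[int(1.0 * sr + tpl.duration * sr) + 2 :] == 0.0)
        inside = wave[int(1.0 * sr) : int((1.0 + tpl.duration) * sr)]
        assert np.max(np.abs(inside)) > 0.01

    def test_waveform_length(self, clean_templates):
        spec = _uniform_spec(4)
        truth = syn.FamilySimulationTruth([], spec, 0)
        wave = syn.render_audio(truth, clean_templates, duration=0.123)
        assert len(wave) == round(0.123 * 125000)

    def test_aliasing_rate_rejected(self, clean_templates):
        spec = _uniform_spec(4)
        truth = syn.FamilySimulationTruth([], spec, 0)
        with pytest.raises(ParameterError):
            syn.render_audio(truth, clean_templates, sample_rate=20000.0)

    def test_roundtrip_onsets_recovered(self, spaced_truth, spaced_session):
        truth, _ = spaced_truth
        _, _, detected = spaced_session
        assert len(detected) == len(truth.events)
        det_on = np.array([e.onset for e in detected])
        errs = [np.min(np.abs(det_on - a)) for a in truth.onsets]
        assert max(errs) < 0.010  # within 10 ms of truth


class TestLatentsFromTruth:
    def _truth(self, clean_templates, n_types=2, hours=0.5, seed=0):
        spec = _uniform_spec(n_types, rate=2000.0)
        return syn.simulate_family(spec, clean_templates, hours, seed=seed)

    def test_zero_scales_hit_means_exactly(self, clean_templates):
        truth = self._truth(clean_templates)
        means = np.array([[0.0, 0.0], [5.0, 5.0]])
        lat = syn.latents_from_truth(truth, means, np.zeros_like(means), seed=0)
        labels = truth.labels[truth.is_vocal]
        assert np.array_equal(lat.z, means[labels])

    def test_separated_means_classified_by_distance(self, clean_templates):
        truth = self._truth(clean_templates)
        means = np.array([[-5.0, -5.0], [5.0, 5.0]])
        lat = syn.latents_from_truth(truth, means, np.ones_like(means), seed=1)
        labels = truth.labels[truth.is_vocal]
        nearest = np.argmin(
            np.linalg.norm(lat.z[:, None, :] - means[None], axis=2), axis=1
        )
        assert np.mean(nearest == labels) >= 0.99

    def test_seed_determinism(self, clean_templates):
        truth = self._truth(clean_templates)
        means = np.zeros((2, 3))
        a = syn.latents_from_truth(truth, means, np.ones_like(means), seed=2)
        b = syn.latents_from_truth(truth, means, np.ones_like(means), seed=2)
        assert np.array_equal(a.z, b.z)

    def test_cohort_is_family(self, clean_templates):
        spec = syn.FamilySpec(
            3, np.array([0.5, 0.5]), np.full((2, 2), 0.5), np.full(24, 500.0)
        )
        truth = syn.simulate_family(spec, clean_templates, 0.2, seed=0)
        lat = syn.latents_from_truth(truth, np.zeros((2, 2)), np.ones((2, 2)))
        assert np.all(lat.cohort_ids == 3)

    def test_shape_mismatch_rejected(self, clean_templates):
        truth = self._truth(clean_templates, n_types=4)
        with pytest.raises(ValueError):
            syn.latents_from_truth(truth, np.zeros((2, 3)), np.ones((2, 3)))


def test_sample_latents_usage_frequencies():
    usage = np.array([0.7, 0.2, 0.1])
    means = np.array([[0.0], [10.0], [20.0]])
    lat = syn.sample_latents(usage, means, 0.1 * np.ones_like(means), 5000, seed=0)
    labels = np.argmin(np.abs(lat.z - means.T), axis=1)
    freq = np.bincount(labels, minlength=3) / 5000
    sd = np.sqrt(usage * (1 - usage) / 5000)
    assert np.all(np.abs(freq - usage) < 3 * sd + 1e-9)
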