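"""Shared fixtures: clean syllable repertoires and rendered sessions.

Audio fixtures are generated programmatically; the "clean" repertoire
uses low-frequency, multi-harmonic, unmodulated templates whose
harmonics stay inside the analysis band, so rendered syllables sit well
above the segmentation thresholds and round-trip tests isolate the
detector rather than template acoustics.
"""

from __future__ import annotations

import numpy as np
import pytest

from vocalscape import synthetic as syn
from vocalscape.params import SegmentationParams

SAMPLE_RATE = 125000.0


@pytest.fixture(scope="session")
def clean_templates() -> list[syn.SyllableTemplate]:
    return [
        syn.SyllableTemplate(
            type_id=i,
            f_start=5000.0 + 3000.0 * i,
            f_end=8000.0 + 3500.0 * i,
            duration=0.04 + 0.012 * i,
            harmonics=3,
            am_depth=0.0,
        )
        for i in range(4)
    ]


@pytest.fixture(scope="session")
def spaced_truth(clean_templates):
    """40 well-separated syllables at known onsets (gaps 0.4-0.7 s)."""
    spec = syn.FamilySpec(
        family_id=0,
        usage=np.full(4, 0.25),
        transition=np.full((4, 4), 0.25),
        diurnal_rate=np.full(24, 100.0),
    )
    rng = np.random.default_rng(7)
    events, t0 = [], 0.5
    for _ in range(40):
        ty = int(rng.integers(4))
        events.append((t0, t0 + clean_templates[ty].duration, ty, True))
        t0 += 0.4 + rng.uniform(0.0, 0.3)
    return syn.FamilySimulationTruth(events, spec, seed=7), t0 + 1.0


@pytest.fixture(scope="session")
def spaced_session(spaced_truth, clean_templates):
    """Rendered audio of the spaced fixture plus its detected events."""
    from vocalscape import segmentation as seg

    truth, duration = spaced_truth
    wave = syn.render_audio(
        truth, clean_templates, noise_floor=1e-3, duration=duration, seed=0
    )
    events = seg.segment_audio(wave, SegmentationParams())
    return truth, wave, events
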