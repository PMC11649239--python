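"""Temporal structure of vocal emission: diurnal cycle, intervals, bouts.

A bout is a maximal run of vocalizations whose consecutive onset-to-onset
gaps are strictly below 2 s, containing at least 5 vocalizations.  Both
criteria are exposed as parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import SoundEvent


@dataclass
class Bout:
    """A maximal run of closely spaced vocalizations."""

    member_events: list[SoundEvent]
    onset: float
    offset: float
    size: int


def hourly_emission(
    onsets: np.ndarray, origin_clock_hour: float = 0.0
) -> np.ndarray:
    """24-bin clock-hour histogram of event onsets, summed over days.

    ``origin_clock_hour`` anchors recording time 0 to a wall-clock hour.
    """
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size == 0:
        return np.zeros(24, dtype=int)
    if np.any(onsets < 0):
        raise ValueError("onsets must be nonnegative")
    hours = (np.floor(onsets / 3600.0 + origin_clock_hour) % 24).astype(int)
    return np.bincount(hours, minlength=24)


def inter_vocalization_intervals(onsets: np.ndarray) -> np.ndarray:
    """Onset-to-onset first differences of a sorted onset array."""
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size and np.any(np.diff(onsets) < 0):
        raise ValueError("onsets must be sorted")
    return np.diff(onsets)


def extract_bouts(
    events: list[SoundEvent],
    max_gap: float = 2.0,
    min_count: int = 5,
) -> tuple[list[Bout], float]:
    """Greedy maximal-run bout extraction.

    Consecutive events belong to the same run iff their onset-to-onset
    gap is strictly below ``max_gap``; runs with at least ``min_count``
    events become bouts.  Returns the bouts and the fraction of all
    events that are bout members (0.0 for empty input).
    """
    if any(events[i].onset > events[i + 1].onset for i in range(len(events) - 1)):
        raise ValueError("events must be sorted by onset")
    bouts: list[Bout] = []
    run: list[SoundEvent] = []
    in_bouts = 0

    def close(run):
        nonlocal in_bouts
        if len(run) >= min_count:
            bouts.append(
                Bout(list(run), run[0].onset, run[-1].offset, len(run))
            )
            in_bouts += len(run)

    for ev in events:
        if run and ev.onset - run[-1].onset >= max_gap:
            close(run)
            run = []
        run.append(ev)
    if run:
        close(run)
    frac = in_bouts / len(events) if events else 0.0
    return bouts, frac


def duration_distribution(events: list[SoundEvent]) -> np.ndarray:
    """Per-event durations (offset - onset), in seconds."""
    return np.array([ev.duration for ev in events])
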