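"""Vocal / non-vocal screening by spectral flatness.

Spectral flatness — the geometric mean of the power spectrum over its
arithmetic mean, averaged across short-time frames — is near 1 for
broadband noise and near 0 for tonal sounds.  Events with flatness
strictly below a threshold (default 0.3) are classified as
vocalizations; the threshold can be calibrated against labeled events by
estimating the false-positive vocalization rate over a grid of candidate
thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hann

from .params import FlatnessParams
from .segmentation import SoundEvent

#: Default calibration grid of candidate flatness thresholds.
DEFAULT_GRID = (0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4)

_AMIN = 1e-30  # power floor inside the geometric mean


class WindowingError(ValueError):
    """Segment shorter than one flatness analysis window."""


def _frame(x: np.ndarray, win: int, hop: int) -> np.ndarray:
    n = 1 + (len(x) - win) // hop
    idx = hop * np.arange(n)[:, None] + np.arange(win)[None, :]
    return x[idx]


def spectral_flatness(
    segment: np.ndarray, params: FlatnessParams | None = None
) -> tuple[float, bool]:
    """Mean across-frame spectral flatness of an audio segment.

    Per frame, flatness = exp(mean(log S)) / mean(S) for the power
    spectrum S of a Hann-windowed frame (non-centered framing).
    Zero-energy frames are excluded from the across-frame mean; an
    all-zero segment returns flatness 1.0 with ``zero_energy=True``.

    Returns
    -------
    (flatness, zero_energy)
    """
    params = params or FlatnessParams()
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 1:
        raise ValueError("segment must be mono")
    if segment.size < params.win_length:
        raise WindowingError(
            f"segment ({segment.size} samples) shorter than win_length "
            f"({params.win_length})"
        )
    frames = _frame(segment, params.win_length, params.hop_length)
    window = hann(params.win_length, sym=False)
    spec = np.abs(np.fft.rfft(frames * window, n=params.n_fft, axis=1))
    power = spec ** params.power
    energies = power.sum(axis=1)
    live = energies > 0
    if not np.any(live):
        return 1.0, True
    power = power[live]
    gmean = np.exp(np.mean(np.log(np.maximum(power, _AMIN)), axis=1))
    amean = np.mean(power, axis=1)
    return float(np.mean(gmean / amean)), False


def classify_event(flatness: float, threshold: float = 0.3) -> bool:
    """True (vocal) iff ``flatness < threshold`` (strict)."""
    if not 0 <= flatness <= 1:
        raise ValueError(f"flatness must be in [0, 1], got {flatness}")
    return flatness < threshold


def screen_events(
    audio: np.ndarray,
    events: list[SoundEvent],
    sample_rate: float,
    threshold: float = 0.3,
    params: FlatnessParams | None = None,
) -> list[SoundEvent]:
    """Fill ``flatness`` and ``is_vocal`` for each detected event in place.

    Events too short for one flatness window are padded with trailing
    zeros up to the window length (their spectra are unaffected by the
    zero tail beyond normalization).
    """
    params = params or FlatnessParams()
    for ev in events:
        a = int(round(ev.onset * sample_rate))
        b = int(round(ev.offset * sample_rate))
        seg = np.asarray(audio[a:b], dtype=float)
        if seg.size < params.win_length:
            seg = np.pad(seg, (0, params.win_length - seg.size))
        ev.flatness, _ = spectral_flatness(seg, params)
        ev.is_vocal = classify_event(ev.flatness, threshold)
    return events


@dataclass
class FPRCurve:
    """False-positive-rate calibration curve over a threshold grid."""

    thresholds: np.ndarray
    mean_fpr: np.ndarray
    sd_fpr: np.ndarray
    short_sample: np.ndarray  # True where fewer events than requested

    def as_dict(self) -> dict[float, tuple[float, float]]:
        return {
            float(t): (float(m), float(s))
            for t, m, s in zip(self.thresholds, self.mean_fpr, self.sd_fpr)
        }


def calibrate_threshold(
    flatness: np.ndarray,
    is_vocal_truth: np.ndarray,
    grid=DEFAULT_GRID,
    samples_per_rep: int = 100,
    reps: int = 10,
    seed: int = 0,
) -> FPRCurve:
    """Estimate the false-positive vocalization rate over a threshold grid.

    For each candidate threshold, repeatedly sample ``samples_per_rep``
    events whose flatness falls below it (without replacement) and record
    the fraction whose true label is non-vocal; the curve reports the
    mean and sd over ``reps`` repetitions.  Grid values with fewer
    qualifying events than requested use all of them, flagged in
    ``short_sample``.
    """
    flatness = np.asarray(flatness, dtype=float)
    truth = np.asarray(is_vocal_truth, dtype=bool)
    if flatness.shape != truth.shape:
        raise ValueError("flatness and labels must align")
    if truth.all() or not truth.any():
        raise ValueError("calibration needs both vocal and non-vocal events")
    rng = np.random.default_rng(seed)
    grid = np.asarray(grid, dtype=float)
    means, sds, short = [], [], []
    for th in grid:
        pool = np.flatnonzero(flatness < th)
        if pool.size == 0:
            means.append(np.nan)
            sds.append(np.nan)
            short.append(True)
            continue
        n = min(samples_per_rep, pool.size)
        short.append(pool.size < samples_per_rep)
        rates = [
            float(np.mean(~truth[rng.choice(pool, size=n, replace=False)]))
            for _ in range(reps)
        ]
        means.append(float(np.mean(rates)))
        sds.append(float(np.std(rates)))
    return FPRCurve(grid, np.array(means), np.array(sds), np.array(short))
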