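"""Amplitude-threshold segmentation of sound events.

Sound events are detected on a smoothed amplitude trace computed from a
band-limited log-modulus spectrogram.  Onsets are marked when the trace
exceeds ``th_3``; an offset is marked at the first subsequent local
minimum below ``th_2``, or when the trace falls below ``th_1``, whichever
comes first.  After an offset, if the trace has not dipped below ``th_3``
a new onset requires the trace to exceed ``th_2``; once the trace falls
below ``th_3`` a new onset again requires crossing ``th_3``.  Detected
events shorter than ``min_dur`` or longer than ``max_dur`` are discarded.

Threshold units: the column-summed trace is centered by its median and
scaled by its median absolute deviation over the processing chunk, so the
integer thresholds act as robust z-scores.  Set
``SegmentationParams.normalize_trace = False`` for raw column sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import stft

from .params import SegmentationParams

_LOG_EPS = 1e-12


class EmptyInputError(ValueError):
    """Audio shorter than one analysis window."""


@dataclass
class SoundEvent:
    """One detected acoustic event, times in seconds from recording start.

    The interval is half-open, ``[onset, offset)``, so
    ``duration == offset - onset``.
    """

    onset: float
    offset: float
    flatness: float = float("nan")
    is_vocal: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.onset < self.offset:
            raise ValueError("need 0 <= onset < offset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class AmplitudeTrace:
    """Per-frame amplitude values plus the frame clock."""

    values: np.ndarray
    frame_rate: float
    origin: float = 0.0  # time of frame 0, s

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace must be finite")

    def frame_time(self, frame: int | np.ndarray) -> float | np.ndarray:
        return self.origin + np.asarray(frame) / self.frame_rate


def compute_spectrogram(
    audio: np.ndarray, params: SegmentationParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Band-limited, clamped log-modulus spectrogram.

    Returns ``(spec, freqs, times)`` where ``spec`` has shape
    ``(n_freqs, n_frames)``, natural-log modulus clamped to
    ``[spec_min_val, spec_max_val]``, rows restricted to
    ``[min_freq, max_freq]``.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.ndim != 1:
        raise ValueError("audio must be mono")
    if audio.size < params.nperseg:
        raise EmptyInputError(
            f"audio ({audio.size} samples) shorter than one window "
            f"({params.nperseg} samples)"
        )
    freqs, times, Z = stft(
        audio,
        fs=params.fs,
        window="hann",
        nperseg=params.nperseg,
        noverlap=params.noverlap,
        boundary=None,
        padded=False,
    )
    band = (freqs >= params.min_freq) & (freqs <= params.max_freq)
    spec = np.log(np.abs(Z[band]) + _LOG_EPS)
    np.clip(spec, params.spec_min_val, params.spec_max_val, out=spec)
    return spec, freqs[band], times


def compute_amplitude_trace(
    spectrogram: np.ndarray,
    params: SegmentationParams,
    origin: float = 0.0,
) -> AmplitudeTrace:
    """Column-sum the spectrogram, normalize to trace units, and smooth.

    Trace units are robust z-scores: ``(sum - median) / MAD`` over the
    chunk (MAD of zero, e.g. a constant spectrogram, falls back to a unit
    scale).  Gaussian smoothing uses
    ``sigma = smoothing_timescale * frame_rate`` frames.
    """
    spectrogram = np.asarray(spectrogram, dtype=float)
    if spectrogram.ndim != 2 or spectrogram.size == 0:
        raise ValueError("spectrogram must be a nonempty 2-D array")
    if params.softmax:
        w = np.exp(spectrogram / params.temperature)
        w /= w.sum(axis=0, keepdims=True)
        trace = (w * spectrogram).sum(axis=0)
    else:
        trace = spectrogram.sum(axis=0)
    if params.normalize_trace:
        med = np.median(trace)
        mad = np.median(np.abs(trace - med))
        trace = (trace - med) / (mad if mad > 0 else 1.0)
    sigma = params.smoothing_timescale * params.frame_rate
    if sigma > 0:
        trace = gaussian_filter1d(trace, sigma)
    return AmplitudeTrace(trace, params.frame_rate, origin)


def _is_local_min(x: np.ndarray, t: int) -> bool:
    # Last frame of a plateau counts as the minimum; endpoints never do.
    return 0 < t < len(x) - 1 and x[t] <= x[t - 1] and x[t] < x[t + 1]


def detect_sound_events(
    trace: AmplitudeTrace, params: SegmentationParams
) -> list[SoundEvent]:
    """Run the three-threshold state machine over an amplitude trace.

    Returns accepted events, ordered and non-overlapping, with durations
    in ``[min_dur, max_dur]``.  An event still open at the end of the
    trace is dropped.
    """
    x = trace.values
    events: list[tuple[int, int]] = []
    IDLE, IN_EVENT, POST = 0, 1, 2
    state = IDLE
    onset = -1
    for t in range(len(x)):
        if state == IDLE:
            if x[t] > params.th_3:
                onset, state = t, IN_EVENT
        elif state == IN_EVENT:
            if x[t] < params.th_1:
                offset = t
            elif x[t] < params.th_2 and _is_local_min(x, t):
                offset = t
            else:
                continue
            events.append((onset, offset))
            state = POST if x[offset] >= params.th_3 else IDLE
        else:  # POST: offset passed but trace never dipped below th_3
            if x[t] < params.th_3:
                state = IDLE
            elif x[t] > params.th_2:
                onset, state = t, IN_EVENT
    out = []
    for a, b in events:
        dur = (b - a) / trace.frame_rate
        if params.min_dur <= dur <= params.max_dur:
            out.append(
                SoundEvent(
                    onset=float(trace.frame_time(a)),
                    offset=float(trace.frame_time(b)),
                )
            )
    return out


@dataclass
class _Chunk:
    start_sample: int
    events: list[SoundEvent] = field(default_factory=list)


def segment_audio(
    audio: np.ndarray,
    params: SegmentationParams,
    chunk_s: float = 300.0,
) -> list[SoundEvent]:
    """Segment a full recording, processing in overlapping chunks.

    Chunks of ``chunk_s`` seconds overlap by ``2 * max_dur`` plus a
    smoothing margin, and each chunk owns the events whose onset falls
    in its non-overlapped core, so events straddling a chunk boundary
    are detected intact by exactly one chunk.  Chunked processing bounds
    memory on long recordings and gives the robust trace normalization a
    stable, local reference level.
    """
    audio = np.asarray(audio, dtype=float)
    chunk_len = int(round(chunk_s * params.fs))
    overlap = int(round((2 * params.max_dur + 20 * params.smoothing_timescale)
                        * params.fs))
    overlap = max(overlap, 2 * params.nperseg)
    if chunk_len <= 2 * overlap:
        raise ValueError("chunk too short for the required overlap")
    events: list[SoundEvent] = []
    start = 0
    while start < audio.size:
        stop = min(audio.size, start + chunk_len)
        piece = audio[start:stop]
        if piece.size < params.nperseg:
            break
        spec, _, times = compute_spectrogram(piece, params)
        origin = start / params.fs + float(times[0])
        trace = compute_amplitude_trace(spec, params, origin=origin)
        own_from = start / params.fs + (overlap / 2) / params.fs if start > 0 else 0.0
        own_to = (
            stop / params.fs - (overlap / 2) / params.fs
            if stop < audio.size
            else float("inf")
        )
        events.extend(
            e
            for e in detect_sound_events(trace, params)
            if own_from <= e.onset < own_to
        )
        if stop == audio.size:
            break
        start = stop - overlap
    events.sort(key=lambda e: e.onset)
    return events
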