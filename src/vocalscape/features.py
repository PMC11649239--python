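"""Per-vocalization acoustic features.

Frame-wise features are computed on a short-time power spectrum
(default nfft=512, hop=256 at 125 kHz) and collapsed to one scalar per
vocalization by the median across frames — except spectral flatness,
which takes the mean across frames and uses its own transform settings
(n_fft=256, hop=128) so the screen and the feature table share a single
flatness definition.

Feature definitions (independent implementations of the conventions of
the standard song-analysis feature suites):

pitch
    Fundamental frequency from the per-frame linear autocorrelation
    (computed via the zero-padded power spectrum); the peak lag within
    the pitch band is refined by parabolic interpolation.  Frames
    shorter than one fundamental period of ``min_freq`` cap the lowest
    measurable pitch at ``rate / (win - 1)``.
goodness_of_pitch
    Height of that autocorrelation peak normalized by lag-zero energy;
    near 0 for noise, near 1 for strongly periodic frames.
amplitude
    ``10 log10`` of per-frame total spectral power (dB-like; doubling
    the waveform adds a constant).
entropy
    Wiener entropy on a log scale: ``ln(geometric mean / arithmetic
    mean)`` of the power spectrum, <= 0, with 0 for perfectly flat
    spectra.
frequency_modulation
    Median absolute frame-to-frame slope of the spectral centroid, in
    Hz/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal.windows import hann

from .params import FlatnessParams
from .screening import spectral_flatness

_EPS = 1e-30


@dataclass
class FeatureRecord:
    """Scalar acoustic features of one vocalization."""

    pitch: float
    amplitude: float
    entropy: float
    frequency_modulation: float
    goodness_of_pitch: float
    flatness: float
    duration: float
    start_freq: float
    stop_freq: float
    pitch_defined: bool = True

    def as_dict(self) -> dict[str, float]:
        return {
            "pitch": self.pitch,
            "amplitude": self.amplitude,
            "entropy": self.entropy,
            "frequency_modulation": self.frequency_modulation,
            "goodness_of_pitch": self.goodness_of_pitch,
            "flatness": self.flatness,
            "duration": self.duration,
            "start_freq": self.start_freq,
            "stop_freq": self.stop_freq,
        }


@dataclass
class StartStop:
    start: float
    stop: float
    degenerate: bool = False


def _frame(x: np.ndarray, win: int, hop: int) -> np.ndarray:
    n = 1 + (len(x) - win) // hop
    idx = hop * np.arange(n)[:, None] + np.arange(win)[None, :]
    return x[idx]


_AC_UPSAMPLE = 4  # sinc interpolation factor for sub-sample period resolution


def _frame_pitch(frame: np.ndarray, rate: float, min_freq: float, max_freq: float):
    """(pitch_hz, goodness) from the linear autocorrelation of one frame."""
    win = len(frame)
    ups = _AC_UPSAMPLE
    spec = np.fft.rfft(frame, n=2 * win)
    # zero-padding the power spectrum sinc-interpolates the
    # autocorrelation onto a 1/ups-sample lag grid
    ac = np.fft.irfft(np.abs(spec) ** 2, n=2 * win * ups)[: win * ups] * ups
    if ac[0] <= 0:
        return np.nan, 0.0
    rate_u = rate * ups
    lag_min = max(2, int(np.ceil(rate_u / max_freq)))
    lag_max = min(win * ups - 2, int(np.floor(rate_u / min_freq)))
    if lag_max <= lag_min:
        return np.nan, 0.0

    def refine(k):
        y0, y1, y2 = ac[k - 1], ac[k], ac[k + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if abs(denom) > _EPS else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
        return k + delta, y1 - 0.25 * (y0 - y2) * delta

    # local maxima of the autocorrelation in the pitch band; taking the
    # SHORTEST lag among near-best peaks avoids period-doubling (octave)
    # errors for near-periodic frames
    peaks = [
        refine(k)
        for k in range(lag_min, lag_max + 1)
        if ac[k] >= ac[k - 1] and ac[k] >= ac[k + 1]
    ]
    if not peaks:
        k = int(np.argmax(ac[lag_min : lag_max + 1])) + lag_min
        peaks = [refine(k)]
    best = max(v for _, v in peaks)
    lag, val = min((p for p in peaks if p[1] >= 0.9 * best), key=lambda p: p[0])
    f_est = rate_u / lag
    goodness = float(np.clip(val / ac[0], 0.0, 1.0))
    # the lag grid is coarse at high frequencies (period ~ few samples);
    # snap to the parabolically refined power-spectrum peak near f_est
    power = np.abs(spec) ** 2
    df = rate / (2 * win)
    lo = max(1, int(np.floor(f_est / 1.2 / df)))
    hi = min(len(power) - 2, int(np.ceil(f_est * 1.2 / df)))
    if hi > lo:
        k = lo + int(np.argmax(power[lo : hi + 1]))
        logp = np.log(np.maximum(power[k - 1 : k + 2], _EPS))
        denom = logp[0] - 2 * logp[1] + logp[2]
        delta = 0.5 * (logp[0] - logp[2]) / denom if abs(denom) > _EPS else 0.0
        f_est = (k + float(np.clip(delta, -0.5, 0.5))) * df
    return f_est, goodness


def compute_features(
    segment: np.ndarray,
    rate: float = 125000.0,
    nfft: int = 512,
    hop: int = 256,
    min_freq: float = 65.0,
    max_freq: float = 62500.0,
    flatness_params: FlatnessParams | None = None,
) -> FeatureRecord:
    """Compute the acoustic feature record of one audio segment."""
    segment = np.asarray(segment, dtype=float)
    if segment.size < nfft:
        raise ValueError(
            f"segment ({segment.size} samples) shorter than one window ({nfft})"
        )
    duration = segment.size / rate
    frames = _frame(segment, nfft, hop)
    window = hann(nfft, sym=False)
    power = np.abs(np.fft.rfft(frames * window, axis=1)) ** 2
    freqs = np.fft.rfftfreq(nfft, 1.0 / rate)
    band = (freqs >= min_freq) & (freqs <= max_freq)
    pband = power[:, band]
    fband = freqs[band]

    energies = pband.sum(axis=1)
    silent = not np.any(energies > 0)
    amplitude = float(np.median(10.0 * np.log10(energies + _EPS)))
    gmean = np.exp(np.mean(np.log(np.maximum(pband, _EPS)), axis=1))
    amean = np.maximum(pband.mean(axis=1), _EPS)
    entropy = float(np.median(np.log(np.maximum(gmean / amean, _EPS))))

    if silent:
        f0_track = np.full(len(frames), np.nan)
        goodness_track = np.zeros(len(frames))
        centroid = np.full(len(frames), np.nan)
    else:
        f0_track = np.empty(len(frames))
        goodness_track = np.empty(len(frames))
        for i, fr in enumerate(frames):
            f0_track[i], goodness_track[i] = _frame_pitch(
                fr * window, rate, min_freq, max_freq
            )
        centroid = (pband * fband).sum(axis=1) / np.maximum(energies, _EPS)

    frame_rate = rate / hop
    if len(frames) >= 2 and not silent:
        fm = float(np.median(np.abs(np.diff(centroid))) * frame_rate)
    else:
        fm = 0.0

    flat, _ = spectral_flatness(
        segment if segment.size >= (flatness_params or FlatnessParams()).win_length
        else np.pad(segment, (0, 256 - segment.size)),
        flatness_params,
    )

    valid = f0_track[np.isfinite(f0_track)]
    pitch = float(np.median(valid)) if valid.size else float("nan")
    ss = start_stop_frequencies(f0_track) if valid.size else StartStop(
        float("nan"), float("nan"), True
    )
    return FeatureRecord(
        pitch=pitch,
        amplitude=amplitude,
        entropy=entropy,
        frequency_modulation=fm,
        goodness_of_pitch=float(np.median(goodness_track)),
        flatness=flat,
        duration=duration,
        start_freq=ss.start,
        stop_freq=ss.stop,
        pitch_defined=not silent and valid.size > 0,
    )


def start_stop_frequencies(f0_track: np.ndarray) -> StartStop:
    """Median fundamental over the first and last thirds of the track.

    Tracks shorter than 3 frames are degenerate: start = stop = overall
    median, flagged.
    """
    track = np.asarray(f0_track, dtype=float)
    track = track[np.isfinite(track)]
    n = len(track)
    if n < 3:
        med = float(np.median(track)) if n else float("nan")
        return StartStop(med, med, degenerate=True)
    third = n // 3
    return StartStop(
        float(np.median(track[:third])), float(np.median(track[-third:]))
    )


def cluster_feature_summary(
    features: pd.DataFrame,
    cluster_ids: np.ndarray,
    probabilities: np.ndarray | None = None,
    top_n: int = 100,
) -> pd.DataFrame:
    """Per-cluster summary over the most probable members.

    For each cluster, the ``top_n`` members with the highest assignment
    probability (all members, flagged, when the cluster is smaller) are
    summarized by median and IQR of every numeric feature column.
    """
    cluster_ids = np.asarray(cluster_ids, dtype=int)
    if len(features) != len(cluster_ids):
        raise ValueError("features and cluster_ids must align")
    if probabilities is None:
        probabilities = np.ones(len(features))
    probabilities = np.asarray(probabilities, dtype=float)
    num = features.select_dtypes(include=[np.number])
    rows = []
    for k in np.unique(cluster_ids):
        mask = cluster_ids == k
        idx = np.flatnonzero(mask)
        order = idx[np.argsort(probabilities[idx])[::-1]]
        chosen = order[:top_n]
        sub = num.iloc[chosen]
        row: dict = {"cluster": int(k), "n_used": len(chosen),
                     "truncated_pool": len(idx) < top_n}
        for col in num.columns:
            row[f"{col}_median"] = float(sub[col].median())
            row[f"{col}_iqr"] = float(
                sub[col].quantile(0.75) - sub[col].quantile(0.25)
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster")
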