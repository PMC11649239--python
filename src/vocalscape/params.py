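"""Parameter blocks for every pipeline stage, with JSON round-tripping.

The segmentation and preprocessing blocks mirror the field-standard
amplitude-segmentation parameter dictionaries key for key, so a
configuration used with other syllable-segmentation tooling transfers
directly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any


class ParameterError(ValueError):
    """An out-of-bounds or inconsistent parameter value."""


@dataclass
class SegmentationParams:
    """Amplitude-threshold segmentation settings.

    Thresholds ``th_1``/``th_2``/``th_3`` are in units of the normalized
    amplitude trace (robust z-scores by default, see
    :func:`vocalscape.segmentation.compute_amplitude_trace`).
    """

    min_freq: float = 500.0        # Hz, lower edge of the analysis band
    max_freq: float = 62500.0      # Hz, upper edge of the analysis band
    nperseg: int = 512             # STFT window length, samples
    noverlap: int = 256            # STFT overlap, samples
    spec_min_val: float = -8.0     # log-modulus clamp floor
    spec_max_val: float = -7.25    # log-modulus clamp ceiling
    fs: float = 125000.0           # audio sample rate, Hz
    th_1: float = 2.0              # offset threshold (hard floor)
    th_2: float = 5.0              # offset-at-local-minimum / re-onset threshold
    th_3: float = 2.0              # onset threshold
    min_dur: float = 0.03          # minimum syllable duration, s
    max_dur: float = 0.3           # maximum syllable duration, s
    smoothing_timescale: float = 0.007  # Gaussian smoothing sigma, s
    softmax: bool = False          # softmax-weight frequency bins in the trace
    temperature: float = 0.5       # softmax temperature
    normalize_trace: bool = True   # robust (median/MAD) trace normalization

    def __post_init__(self) -> None:
        if not self.min_freq < self.max_freq:
            raise ParameterError("min_freq must be < max_freq")
        if not 0 <= self.noverlap < self.nperseg:
            raise ParameterError("need 0 <= noverlap < nperseg")
        if not self.min_dur < self.max_dur:
            raise ParameterError("min_dur must be < max_dur")
        if self.spec_min_val >= self.spec_max_val:
            raise ParameterError("spec_min_val must be < spec_max_val")
        if self.fs <= 0 or self.smoothing_timescale < 0:
            raise ParameterError("fs must be positive, smoothing nonnegative")

    @property
    def frame_rate(self) -> float:
        """Spectrogram frames per second."""
        return self.fs / (self.nperseg - self.noverlap)


@dataclass
class PreprocessParams:
    """Syllable-spectrogram preprocessing for the latent embedding.

    Produces square log-spectrogram images rescaled to [0, 1]; short
    syllables are stretched to fill the time axis when ``time_stretch``
    is set.
    """

    image_size: int = 128
    max_dur: float = 0.3
    min_freq: float = 500.0
    max_freq: float = 62500.0
    nperseg: int = 512
    noverlap: int = 256
    spec_min_val: float = -8.0
    spec_max_val: float = -5.0
    fs: float = 125000.0
    mel: bool = False
    time_stretch: bool = True
    within_syll_normalize: bool = False

    def __post_init__(self) -> None:
        if self.spec_min_val >= self.spec_max_val:
            raise ParameterError("empty clamp range")
        if self.image_size < 1:
            raise ParameterError("image_size must be >= 1")
        if self.mel:
            raise ParameterError("mel frequency spacing is not supported")


@dataclass
class FlatnessParams:
    """Spectral-flatness transform settings (vocal / non-vocal screen)."""

    n_fft: int = 256
    hop_length: int = 128
    win_length: int = 256
    center: bool = False
    power: float = 2.0

    def __post_init__(self) -> None:
        if not self.hop_length <= self.win_length <= self.n_fft:
            raise ParameterError("need hop_length <= win_length <= n_fft")


@dataclass
class GMMConfig:
    """Cohort mixture-model settings."""

    K: int = 70
    D: int = 7
    mean_prior_sd: float = 5.0
    scale_prior_sd: float = 3.0
    usage_concentration: float = 1.0
    restarts: int = 5
    max_iter: int = 200
    tol: float = 1e-6
    seed: int = 0


@dataclass
class MMDConfig:
    """Kernel two-sample test settings."""

    batch_size: int = 1000
    n_permutations: int = 1000
    bandwidth: float | None = None  # None -> median heuristic per comparison


@dataclass
class TransitionConfig:
    """Transition-analysis settings."""

    n_shuffles: int = 1000
    alpha: float = 0.05
    edge_min: float = 0.001
    method: str = "empirical"      # or "t_test"
    break_at_gaps: bool = False    # optionally break sequences at gaps > 2 s


@dataclass
class PipelineConfig:
    """Full pipeline configuration; serializes losslessly to JSON."""

    seg_params: SegmentationParams = field(default_factory=SegmentationParams)
    preprocess_params: PreprocessParams = field(default_factory=PreprocessParams)
    flatness_params: FlatnessParams = field(default_factory=FlatnessParams)
    flatness_threshold: float = 0.3
    gmm: GMMConfig = field(default_factory=GMMConfig)
    mmd: MMDConfig = field(default_factory=MMDConfig)
    transition: TransitionConfig = field(default_factory=TransitionConfig)
    origin_clock_hour: float = 0.0  # wall-clock hour of recording start

    def __post_init__(self) -> None:
        if not 0 < self.flatness_threshold <= 1:
            raise ParameterError("flatness_threshold must be in (0, 1]")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        return cls(
            seg_params=SegmentationParams(**d.pop("seg_params", {})),
            preprocess_params=PreprocessParams(**d.pop("preprocess_params", {})),
            flatness_params=FlatnessParams(**d.pop("flatness_params", {})),
            gmm=GMMConfig(**d.pop("gmm", {})),
            mmd=MMDConfig(**d.pop("mmd", {})),
            transition=TransitionConfig(**d.pop("transition", {})),
            **d,
        )

    @classmethod
    def from_json(cls, source: str) -> "PipelineConfig":
        """Load from a JSON string or a path to a JSON file."""
        try:
            data = json.loads(source)
        except (json.JSONDecodeError, TypeError):
            with open(source) as fh:
                data = json.load(fh)
        return cls.from_dict(data)
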