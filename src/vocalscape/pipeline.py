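"""Audio I/O, segment-table persistence, accounting, and orchestration.

The pipeline runs segment -> screen -> embed -> cluster -> compare ->
temporal -> transitions over audio (or starts from precomputed latents),
keeps a per-stage structured log of counts in/out, and reports event
accounting — total events, vocal/non-vocal counts, vocal proportion and
per-hour rates — as a partition of the detected events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from . import comparison, mixture, screening, segmentation, temporal, transitions
from .embedding import LatentDataset, encode, select_top_latents, preprocess_segment, train_vae
from .params import PipelineConfig
from .segmentation import SoundEvent


class AudioFormatError(ValueError):
    """Channel length/rate mismatch or unreadable audio."""


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained on .report."""

    def __init__(self, stage: str, cause: Exception, report=None):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.report = report


@dataclass
class AudioRecording:
    """Mono audio with its sample rate and experiment-time origin."""

    samples: np.ndarray
    sample_rate: float = 125000.0
    origin_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise AudioFormatError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise AudioFormatError("samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


def _load_wav(path) -> tuple[float, np.ndarray]:
    try:
        rate, data = wavfile.read(path)
    except (OSError, ValueError) as exc:
        raise AudioFormatError(f"cannot read {path}: {exc}") from exc
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return float(rate), data.astype(float)


def read_audio(source, origin_time: float = 0.0) -> AudioRecording:
    """Read audio and average channels to a single mono signal.

    ``source`` may be a path to a (possibly multichannel) WAV file, a
    list of single-channel WAV paths, a numpy array (1-D mono or
    ``(n, channels)``), or a list of equal-length 1-D arrays.  Arrays
    assume the 125 kHz default rate.
    """
    rate = 125000.0
    if isinstance(source, (str, Path)):
        rate, data = _load_wav(source)
    elif isinstance(source, np.ndarray):
        data = np.asarray(source, dtype=float)
    elif isinstance(source, (list, tuple)):
        if all(isinstance(s, (str, Path)) for s in source):
            rates, chans = zip(*(_load_wav(p) for p in source))
            if len(set(rates)) != 1:
                raise AudioFormatError("channel sample rates differ")
            rate = rates[0]
        else:
            chans = [np.asarray(c, dtype=float) for c in source]
        if len({len(c) for c in chans}) != 1:
            raise AudioFormatError("channel lengths differ")
        data = np.stack(chans, axis=1)
    else:
        raise TypeError(f"unsupported audio source {type(source)}")
    if data.ndim == 2:
        data = data.mean(axis=1)
    elif data.ndim != 1:
        raise AudioFormatError("audio must be 1-D or (n, channels)")
    return AudioRecording(data, rate, origin_time)


def write_wav(path, samples: np.ndarray, sample_rate: float = 125000.0) -> None:
    """Write a float32 mono WAV file."""
    wavfile.write(path, int(sample_rate), np.asarray(samples, dtype=np.float32))


# --------------------------------------------------------------------------
# segment tables
# --------------------------------------------------------------------------

def events_to_frame(events: list[SoundEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "onset_s": [e.onset for e in events],
            "offset_s": [e.offset for e in events],
            "flatness": [e.flatness for e in events],
            "is_vocal": [e.is_vocal for e in events],
        }
    )


def write_segments(path, events: list[SoundEvent]) -> None:
    events_to_frame(events).to_csv(path, index=False)


def read_segments(path) -> list[SoundEvent]:
    df = pd.read_csv(path)
    return [
        SoundEvent(
            onset=row.onset_s,
            offset=row.offset_s,
            flatness=float(row.flatness) if "flatness" in df else float("nan"),
            is_vocal=bool(row.is_vocal) if "is_vocal" in df else False,
        )
        for row in df.itertuples()
    ]


# --------------------------------------------------------------------------
# accounting
# --------------------------------------------------------------------------

@dataclass
class EventAccounting:
    """Partition accounting of detected events over a recording period."""

    vocal_count: int
    nonvocal_count: int
    recorded_hours: float

    @property
    def total_events(self) -> int:
        return self.vocal_count + self.nonvocal_count

    @property
    def vocal_proportion_pct(self) -> float:
        return 100.0 * self.vocal_count / self.total_events if self.total_events else 0.0

    @property
    def events_per_hour(self) -> float:
        return self.total_events / self.recorded_hours

    @property
    def vocal_per_hour(self) -> float:
        return self.vocal_count / self.recorded_hours

    def as_dict(self) -> dict:
        return {
            "total_events": self.total_events,
            "vocal_count": self.vocal_count,
            "nonvocal_count": self.nonvocal_count,
            "vocal_proportion_pct": self.vocal_proportion_pct,
            "events_per_hour": self.events_per_hour,
            "vocal_per_hour": self.vocal_per_hour,
            "recorded_hours": self.recorded_hours,
        }


def event_accounting(
    vocal_count: int, nonvocal_count: int, recorded_hours: float
) -> EventAccounting:
    """Build the event-accounting report from per-class counts.

    The partition identity ``vocal + nonvocal = total`` holds by
    construction; rates are counts over recorded hours.
    """
    if recorded_hours <= 0:
        raise ValueError("recorded_hours must be positive")
    if min(vocal_count, nonvocal_count) < 0:
        raise ValueError("counts must be nonnegative")
    return EventAccounting(int(vocal_count), int(nonvocal_count), float(recorded_hours))


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

@dataclass
class PipelineReport:
    """Artifacts and accounting from one pipeline run."""

    accounting: EventAccounting | None = None
    events: list[SoundEvent] = field(default_factory=list)
    latents: LatentDataset | None = None
    selected_dims: np.ndarray | None = None
    gmm: mixture.CohortGMMParams | None = None
    usage: np.ndarray | None = None
    mmd: dict = field(default_factory=dict)
    hourly: np.ndarray | None = None
    bouts: list = field(default_factory=list)
    fraction_in_bouts: float | None = None
    transition: dict = field(default_factory=dict)
    log: list[dict] = field(default_factory=list)


def _onsets_to_events(onsets: np.ndarray, dur: float = 0.05) -> list[SoundEvent]:
    return [SoundEvent(float(o), float(o) + dur) for o in np.sort(onsets)]


def run_pipeline(
    config: PipelineConfig,
    audio: AudioRecording | None = None,
    latents: LatentDataset | None = None,
    recorded_hours: float | None = None,
    seed: int = 0,
    train_embedding: bool = False,
    embed_opts: dict | None = None,
    out_dir=None,
) -> PipelineReport:
    """Run the full analysis over audio and/or precomputed latents.

    With ``audio``, events are segmented and screened and the accounting
    report is produced; with ``train_embedding`` the vocal events are
    additionally embedded to latents (``embed_opts`` tunes epochs /
    hidden sizes for desk-scale runs).  With ``latents`` (given or
    computed), the cohort mixture, repertoire comparisons, temporal and
    transition analyses run.  Any stage failure raises
    :class:`PipelineStageError` carrying the partial report.
    """
    if audio is None and latents is None:
        raise ValueError("need at least one input source (audio or latents)")
    report = PipelineReport()
    rng = np.random.default_rng(seed)

    def stage(name):
        def deco(fn):
            try:
                n_before = len(report.events)
                fn()
                report.log.append({"stage": name, "events": len(report.events),
                                   "delta": len(report.events) - n_before})
            except Exception as exc:  # noqa: BLE001 - tagged and re-raised
                raise PipelineStageError(name, exc, report) from exc
        return deco

    if audio is not None:
        @stage("segment")
        def _():
            report.events = segmentation.segment_audio(
                audio.samples, config.seg_params
            )

        @stage("screen")
        def _():
            screening.screen_events(
                audio.samples,
                report.events,
                audio.sample_rate,
                threshold=config.flatness_threshold,
                params=config.flatness_params,
            )

        hours = recorded_hours or audio.duration / 3600.0
        n_vocal = sum(e.is_vocal for e in report.events)
        report.accounting = event_accounting(
            n_vocal, len(report.events) - n_vocal, hours
        )

        if train_embedding and latents is None:
            @stage("embed")
            def _():
                opts = dict(embed_opts or {})
                vocal = [e for e in report.events if e.is_vocal]
                images = np.stack(
                    [
                        preprocess_segment(
                            audio.samples, e.onset, e.offset, config.preprocess_params
                        )
                        for e in vocal
                    ]
                )
                model = train_vae(
                    images,
                    epochs=opts.pop("epochs", 50),
                    seed=int(rng.integers(2 ** 31)),
                    image_size=config.preprocess_params.image_size,
                    **opts,
                )
                nonlocal_latents = encode(
                    model, images, onsets=np.array([e.onset for e in vocal])
                )
                report.latents = nonlocal_latents
            latents = report.latents

    if latents is not None:
        report.latents = latents

        @stage("select_latents")
        def _():
            report.selected_dims = select_top_latents(latents)

        reduced = latents.select_dims(report.selected_dims)

        @stage("cluster")
        def _():
            report.gmm = mixture.fit(
                reduced,
                K=min(config.gmm.K, max(1, len(reduced) // 10)),
                seed=int(rng.integers(2 ** 31)),
                restarts=config.gmm.restarts,
                max_iter=config.gmm.max_iter,
            )
            report.usage, _, _ = mixture.cluster_usage(
                report.gmm.assignments, reduced.cohort_ids, report.gmm.K
            )

        if latents.n_cohorts >= 2:
            @stage("compare")
            def _():
                for i in range(latents.n_cohorts):
                    for j in range(i + 1, latents.n_cohorts):
                        res = comparison.mmd_permutation_test(
                            latents.z[latents.cohort_ids == i],
                            latents.z[latents.cohort_ids == j],
                            batch_size=config.mmd.batch_size,
                            n_permutations=config.mmd.n_permutations,
                            seed=int(rng.integers(2 ** 31)),
                            bandwidth=config.mmd.bandwidth,
                        )
                        report.mmd[(i, j)] = res

        if latents.onsets is not None:
            @stage("temporal")
            def _():
                onsets = np.sort(np.asarray(latents.onsets, dtype=float))
                report.hourly = temporal.hourly_emission(
                    onsets, config.origin_clock_hour
                )
                report.bouts, report.fraction_in_bouts = temporal.extract_bouts(
                    _onsets_to_events(onsets)
                )

            if report.gmm is not None:
                @stage("transitions")
                def _():
                    for i in range(latents.n_cohorts):
                        mask = latents.cohort_ids == i
                        order = np.argsort(np.asarray(latents.onsets)[mask])
                        seq = report.gmm.assignments[mask][order]
                        if len(seq) < 2:
                            continue
                        tm = transitions.transition_counts(seq, K=report.gmm.K)
                        null = transitions.shuffle_null(
                            seq,
                            n_shuffles=config.transition.n_shuffles,
                            seed=int(rng.integers(2 ** 31)),
                            K=report.gmm.K,
                        )
                        sig = transitions.transition_significance(
                            tm, null,
                            alpha=config.transition.alpha,
                            method=config.transition.method,
                        )
                        graph = transitions.bigram_graph(
                            tm.joint_ij, config.transition.edge_min
                        )
                        report.transition[i] = {
                            "matrix": tm, "significance": sig, "graph": graph
                        }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if report.events:
            write_segments(out / "segments.csv", report.events)
        if report.accounting is not None:
            pd.Series(report.accounting.as_dict()).to_json(out / "accounting.json")
        if report.latents is not None:
            report.latents.to_hdf5(out / "latents.h5")
        if report.usage is not None:
            np.savetxt(out / "cluster_usage.csv", report.usage, delimiter=",")
    return report
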