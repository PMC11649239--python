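"""Segment the rendered excerpt and screen vocal vs non-vocal events.

Reads the excerpt written by 01_simulate_soundscape.py, runs the
three-threshold amplitude segmentation and the spectral-flatness screen,
and reports the event accounting against ground truth.
"""

import argparse
from pathlib import Path

import pandas as pd

from vocalscape import pipeline, screening, segmentation
from vocalscape.params import PipelineConfig

ap = argparse.ArgumentParser()
ap.add_argument("--sim", type=Path, default=Path("scratch/simulation"))
ap.add_argument("--out", type=Path, default=Path("results/segmentation"))
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

cfg = PipelineConfig()
rec = pipeline.read_audio(args.sim / "family0_excerpt.wav")
events = segmentation.segment_audio(rec.samples, cfg.seg_params)
screening.screen_events(
    rec.samples, events, rec.sample_rate, cfg.flatness_threshold, cfg.flatness_params
)
pipeline.write_segments(args.out / "segments.csv", events)

n_vocal = sum(e.is_vocal for e in events)
acc = pipeline.event_accounting(n_vocal, len(events) - n_vocal, rec.duration / 3600)
pd.Series(acc.as_dict()).to_json(args.out / "accounting.json", indent=2)

truth = pd.read_csv(args.sim / "family0_excerpt_truth.csv")
print(
    f"detected {acc.total_events} events ({acc.vocal_proportion_pct:.1f}% vocal) "
    f"vs {len(truth)} true events ({int(truth.is_vocal.sum())} vocal); "
    f"rate {acc.events_per_hour:.0f}/h"
)
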