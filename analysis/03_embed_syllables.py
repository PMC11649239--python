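"""Embed screened vocal segments with the VAE and select top latents.

Preprocesses each vocal event of the excerpt to a 128x128 log-
spectrogram, trains a small VAE, and writes posterior-mean latents plus
the top-variance latent subset.  Desk-scale settings (small hidden
layers, few epochs) keep this a minutes-long run; the statistical
stages downstream consume latents regardless of encoder size.
"""

import argparse
from pathlib import Path

import numpy as np

from vocalscape import embedding as emb, pipeline
from vocalscape.params import PipelineConfig

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--seg", type=Path, default=Path("results/segmentation"))
ap.add_argument("--sim", type=Path, default=Path("scratch/simulation"))
ap.add_argument("--out", type=Path, default=Path("scratch/embedding"))
ap.add_argument("--epochs", type=int, default=10)
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

cfg = PipelineConfig()
rec = pipeline.read_audio(args.sim / "family0_excerpt.wav")
events = [e for e in pipeline.read_segments(args.seg / "segments.csv") if e.is_vocal]
images = np.stack([
    emb.preprocess_segment(rec.samples, e.onset, e.offset, cfg.preprocess_params)
    for e in events
])
model = emb.train_vae(images, epochs=args.epochs, seed=args.seed)
latents = emb.encode(model, images, onsets=np.array([e.onset for e in events]))
latents.to_hdf5(args.out / "latents.h5")
dims = emb.select_top_latents(latents)
np.savetxt(args.out / "selected_dims.csv", dims, fmt="%d")
print(
    f"embedded {len(events)} vocal events; final loss {model.loss_history[-1]:.0f}; "
    f"{len(dims)} of 32 latents explain 99.5% of latent variance"
)
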