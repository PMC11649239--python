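"""Temporal and transition structure of the simulated families.

Diurnal emission histograms, inter-vocalization intervals, bout
extraction, per-family transition matrices with shuffle-null
significance, and bigram graph export (GraphML).
"""

import argparse
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from vocalscape import temporal, transitions
from vocalscape.segmentation import SoundEvent

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--sim", type=Path, default=Path("scratch/simulation"))
ap.add_argument("--out", type=Path, default=Path("results/temporal"))
ap.add_argument("--shuffles", type=int, default=500)
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

for i in range(3):
    truth = pd.read_csv(args.sim / f"family{i}_truth.csv")
    voc = truth[truth.is_vocal].sort_values("onset_s")
    onsets = voc.onset_s.to_numpy()

    hist = temporal.hourly_emission(onsets)
    np.savetxt(args.out / f"family{i}_hourly.csv", hist, fmt="%d")

    events = [SoundEvent(a, b) for a, b in zip(voc.onset_s, voc.offset_s)]
    bouts, frac = temporal.extract_bouts(events)
    pd.DataFrame(
        [(k, b.onset, b.offset, b.size) for k, b in enumerate(bouts)],
        columns=["bout_id", "onset_s", "offset_s", "size"],
    ).to_csv(args.out / f"family{i}_bouts.csv", index=False)

    labels = voc.type_id.to_numpy()
    tm = transitions.transition_counts(labels)
    null = transitions.shuffle_null(labels, n_shuffles=args.shuffles,
                                    seed=args.seed + i, K=tm.K)
    sig = transitions.transition_significance(tm, null, method="empirical")
    np.savetxt(args.out / f"family{i}_transition_p.csv", tm.p_ij, delimiter=",")
    np.savetxt(args.out / f"family{i}_significant.csv",
               sig.significant.astype(int), delimiter=",", fmt="%d")
    G = transitions.bigram_graph(tm.joint_ij)
    nx.write_graphml(G, args.out / f"family{i}_bigram.graphml")

    self_frac = np.mean(labels[:-1] == labels[1:])
    print(
        f"family {i}: {len(events)} vocalizations, {len(bouts)} bouts "
        f"({100 * frac:.1f}% of vocalizations in bouts), "
        f"self-transition fraction {self_frac:.2f}, "
        f"{int(sig.significant.sum())} transitions above chance"
    )
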