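"""Vocal-cluster transition structure with shuffle-based null testing.

Cluster labels concatenated chronologically form a sequence whose bigram
counts give a transition matrix: ``p_ij`` (row-normalized, the
probability that cluster ``i`` is followed by cluster ``j``) and
``joint_ij`` (pair proportions summing to 1).  Whether an observed
transition occurs above chance is tested against a null built from
uniformly shuffled label sequences — shuffling preserves the label
multiset (1-gram usage) exactly, so any flagged structure is genuinely
sequential.  P-values are corrected with Benjamini-Hochberg across all
K^2 transitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class TransitionMatrix:
    """Bigram counts and normalized transition probabilities."""

    counts: np.ndarray          # (K, K) integer bigram counts
    p_ij: np.ndarray            # row-normalized; zero rows stay zero
    joint_ij: np.ndarray        # pair proportions, sums to 1
    sequence_length: int
    empty: bool = False         # sequence too short for any transition

    @property
    def K(self) -> int:
        return self.counts.shape[0]


@dataclass
class TransitionNull:
    """Shuffle-null samples and per-transition significance calls."""

    null_p: np.ndarray          # (n_shuffles, K, K) null p_ij samples
    p_values: np.ndarray | None = None
    significant: np.ndarray | None = None
    alpha: float = 0.05

    @property
    def n_shuffles(self) -> int:
        return self.null_p.shape[0]


def transition_counts(labels: np.ndarray, K: int | None = None) -> TransitionMatrix:
    """Tally bigram transitions of a chronological label sequence.

    Labels are 0-based cluster indices.  ``counts[a, b]`` is the number
    of positions where label ``a`` is immediately followed by ``b``.
    Sequences shorter than 2 produce an all-zero matrix flagged
    ``empty``.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size and labels.min() < 0:
        raise ValueError("labels must be nonnegative cluster indices")
    if K is None:
        K = int(labels.max()) + 1 if labels.size else 1
    counts = np.zeros((K, K), dtype=int)
    if labels.size >= 2:
        np.add.at(counts, (labels[:-1], labels[1:]), 1)
    total = counts.sum()
    row = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_ij = np.where(row > 0, counts / np.maximum(row, 1), 0.0)
    joint = counts / total if total > 0 else np.zeros_like(counts, dtype=float)
    return TransitionMatrix(
        counts=counts,
        p_ij=p_ij,
        joint_ij=joint,
        sequence_length=int(labels.size),
        empty=total == 0,
    )


def shuffle_null(
    labels: np.ndarray,
    n_shuffles: int = 1000,
    seed: int = 0,
    K: int | None = None,
) -> TransitionNull:
    """Null transition-probability distribution from shuffled sequences.

    Each shuffle is a uniform permutation of the full label sequence, so
    the label multiset (and hence 1-gram usage) is preserved exactly.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size < 2:
        raise ValueError("sequence must have length >= 2")
    if K is None:
        K = int(labels.max()) + 1
    rng = np.random.default_rng(seed)
    null = np.empty((n_shuffles, K, K))
    for s in range(n_shuffles):
        null[s] = transition_counts(rng.permutation(labels), K=K).p_ij
    return TransitionNull(null_p=null)


def transition_significance(
    observed: TransitionMatrix,
    null: TransitionNull,
    alpha: float = 0.05,
    method: str = "empirical",
) -> TransitionNull:
    """Flag transitions occurring above chance, with BH correction.

    ``t_test``: two-sided one-sample t-test of the null sample against
    the observed value; only transitions with observed above the null
    mean can be flagged.  ``empirical``: add-one upper-tail percentile
    p-value, ``(1 + #{null >= obs}) / (1 + n_shuffles)``.  Rows with no
    outgoing counts are excluded from testing (p = 1, never flagged).
    Benjamini-Hochberg runs across all tested transitions; the binary
    matrix flags adjusted p <= alpha.
    """
    if method not in ("empirical", "t_test"):
        raise ValueError(f"unknown method {method!r}")
    K = observed.K
    obs = observed.p_ij
    nullv = null.null_p
    n_sh = null.n_shuffles
    testable = np.repeat(observed.counts.sum(axis=1) > 0, K).reshape(K, K)
    pvals = np.ones((K, K))
    above = np.zeros((K, K), dtype=bool)
    for a in range(K):
        for b in range(K):
            if not testable[a, b]:
                continue
            sample = nullv[:, a, b]
            above[a, b] = obs[a, b] > sample.mean()
            if method == "empirical":
                pvals[a, b] = (1 + np.sum(sample >= obs[a, b])) / (1 + n_sh)
            else:
                if np.ptp(sample) == 0:
                    pvals[a, b] = 1.0 if sample[0] == obs[a, b] else 0.0
                else:
                    pvals[a, b] = stats.ttest_1samp(sample, obs[a, b]).pvalue
    flat = pvals[testable]
    reject = np.zeros_like(flat, dtype=bool)
    if flat.size:
        reject, p_adj, _, _ = multipletests(flat, alpha=alpha, method="fdr_bh")
        padj_full = np.ones((K, K))
        padj_full[testable] = p_adj
    sig = np.zeros((K, K), dtype=bool)
    sig[testable] = reject
    if method == "t_test":
        sig &= above
    else:
        # the empirical p is already one-sided (upper tail)
        pass
    return TransitionNull(
        null_p=nullv, p_values=pvals, significant=sig, alpha=alpha
    )


def bigram_graph(joint_ij: np.ndarray, min_edge: float = 0.001) -> nx.DiGraph:
    """Weighted directed bigram graph of frequent cluster pairs.

    Edges carry the pair probability ``joint_ij[a, b]``; only edges
    strictly above ``min_edge`` are retained, and only clusters with a
    retained edge appear as nodes.  Each node's ``weight`` attribute is
    its total incident pair probability.
    """
    joint = np.asarray(joint_ij, dtype=float)
    total = joint.sum()
    if total > 0 and not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError("joint_ij must sum to 1")
    G = nx.DiGraph()
    K = joint.shape[0]
    for a in range(K):
        for b in range(K):
            if joint[a, b] > min_edge:
                G.add_edge(a, b, weight=float(joint[a, b]))
    for node in G.nodes:
        w = sum(d["weight"] for _, _, d in G.in_edges(node, data=True))
        w += sum(d["weight"] for _, _, d in G.out_edges(node, data=True))
        G.nodes[node]["weight"] = w
    return G
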