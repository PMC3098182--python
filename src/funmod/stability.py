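"""Cross-run topic stability: KL-based matching and circular chain tracking.

Independent Gibbs chains started from different seeds permute and perturb
the recovered topics.  To decide which topics are reproducible, topic-term
distributions from two runs are compared all-against-all with the
symmetrized Kullback-Leibler divergence (Jeffreys divergence,
KL(p||q) + KL(q||p), in nats) and paired greedily: the globally smallest
divergence among still-unmatched topics is accepted first, repeatedly.  This
best-first pairing is a local optimum and can miss the assignment with the
smallest total divergence; it is kept as the method's matching rule, with
the optimal assignment available only as a cross-check in tests.

A topic of run 1 is *stable* over runs 1..N when composing the pairwise
mappings run1->run2->...->runN->run1 returns to the starting topic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import rel_entr


@dataclass(frozen=True)
class TopicMapping:
    """Greedy pairing of topics between two runs.

    ``pairs`` lists (topic_in_a, topic_in_b, divergence) in acceptance order,
    which is non-decreasing divergence order; topics left over when the runs
    have different k are in ``unmatched_a`` / ``unmatched_b``.
    """

    run_a: int
    run_b: int
    pairs: list[tuple[int, int, float]]
    unmatched_a: list[int]
    unmatched_b: list[int]

    def as_dict(self) -> dict[int, int]:
        return {a: b for a, b, _ in self.pairs}


@dataclass(frozen=True)
class StableTopicSet:
    """Circularly closed topic chains; each chain has one index per run."""

    chains: list[list[int]]
    n_runs: int

    @property
    def stable_run0_topics(self) -> list[int]:
        return [chain[0] for chain in self.chains]


def symmetrized_kl(p: np.ndarray, q: np.ndarray) -> float:
    """Jeffreys divergence KL(p||q) + KL(q||p) in nats.

    Both vectors must be strictly positive (Dirichlet smoothing guarantees
    this for estimated topic distributions) and sum to one.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    if np.any(p <= 0) or np.any(q <= 0):
        raise ValueError("entries must be strictly positive (smoothing contract)")
    if not (abs(p.sum() - 1) < 1e-6 and abs(q.sum() - 1) < 1e-6):
        raise ValueError("p and q must each sum to 1")
    return float(rel_entr(p, q).sum() + rel_entr(q, p).sum())


def _divergence_matrix(phi_a: np.ndarray, phi_b: np.ndarray) -> np.ndarray:
    # sum_w (p-q) ln(p/q), vectorized over all topic pairs
    log_a = np.log(phi_a)
    log_b = np.log(phi_b)
    # KL(a_i || b_j) = sum p_i (log p_i - log b_j)
    kl_ab = (phi_a * log_a).sum(axis=1)[:, None] - phi_a @ log_b.T
    kl_ba = (phi_b * log_b).sum(axis=1)[None, :] - (phi_b @ log_a.T).T
    return kl_ab + kl_ba


def greedy_match(div: np.ndarray) -> list[tuple[int, int, float]]:
    """Best-first pairing on a divergence matrix.

    Repeatedly accepts the globally smallest entry whose row and column are
    both unmatched; ties break on (row index, column index).  Accepts exactly
    min(k_a, k_b) pairs.
    """
    div = np.asarray(div, dtype=float)
    ka, kb = div.shape
    work = div.copy()
    pairs: list[tuple[int, int, float]] = []
    for _ in range(min(ka, kb)):
        flat = int(np.argmin(work))  # row-major argmin = (a, b) tie-break
        a, b = divmod(flat, kb)
        pairs.append((a, b, float(div[a, b])))
        work[a, :] = np.inf
        work[:, b] = np.inf
    return pairs


def match_topics(
    phi_a: np.ndarray,
    phi_b: np.ndarray,
    run_a: int = 0,
    run_b: int = 1,
) -> TopicMapping:
    """All-against-all symmetrized-KL comparison followed by greedy pairing."""
    phi_a = np.asarray(phi_a, dtype=float)
    phi_b = np.asarray(phi_b, dtype=float)
    if phi_a.shape[1] != phi_b.shape[1]:
        raise ValueError("runs must share the same vocabulary ordering")
    pairs = greedy_match(_divergence_matrix(phi_a, phi_b))
    matched_a = {a for a, _, _ in pairs}
    matched_b = {b for _, b, _ in pairs}
    return TopicMapping(
        run_a=run_a,
        run_b=run_b,
        pairs=pairs,
        unmatched_a=[a for a in range(phi_a.shape[0]) if a not in matched_a],
        unmatched_b=[b for b in range(phi_b.shape[0]) if b not in matched_b],
    )


def track_stable_topics(runs: list[np.ndarray]) -> StableTopicSet:
    """Compose run1->run2->...->runN->run1 mappings and keep closed chains."""
    if len(runs) < 2:
        raise ValueError("need at least 2 runs to track stability")
    n = len(runs)
    hops = [
        match_topics(runs[i], runs[(i + 1) % n], i, (i + 1) % n).as_dict()
        for i in range(n)
    ]
    chains: list[list[int]] = []
    for start in range(runs[0].shape[0]):
        chain = [start]
        cur = start
        ok = True
        for hop in hops:
            if cur not in hop:
                ok = False
                break
            cur = hop[cur]
            chain.append(cur)
        if ok and cur == start:
            chains.append(chain[:-1])  # drop the closing return to run 0
    return StableTopicSet(chains=chains, n_runs=n)
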