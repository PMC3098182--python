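"""Synthetic corpora from planted functional modules, for end-to-end testing.

The generative process mirrors the model's own assumptions: each planted
module is a probability distribution over the descriptor vocabulary that
concentrates most mass on a small member-term set (near-uniform within
members, with a configurable background mass spread over the remaining
vocabulary); each genome document draws a module-mixture weight vector and
then samples its tokens module-first, term-second.  A matched synthetic
reference network and channel-score table let the whole evaluation pipeline
run without external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from funmod.corpus_io import AnnotationCorpus
from funmod.evaluation import CHANNELS
from funmod.module_extraction import PFModule


@dataclass(frozen=True)
class PlantedModel:
    """Ground truth for a synthetic corpus.

    ``phi_star`` rows sum to one; member terms of module i jointly receive at
    least (1 - background_mass) of row i's probability.
    """

    vocabulary: list[str]
    module_members: list[frozenset[str]]
    phi_star: np.ndarray

    @property
    def k_true(self) -> int:
        return len(self.module_members)


def generate_planted_model(
    vocab_size: int,
    k_true: int,
    module_size_range: tuple[int, int] = (5, 60),
    background_mass: float = 0.02,
    overlap_terms: int = 0,
    member_concentration: float = 50.0,
    seed: int = 0,
) -> PlantedModel:
    """Plant ``k_true`` modules with near-uniform within-member probabilities.

    Member sets are disjoint except for ``overlap_terms`` shared terms per
    adjacent module pair (emulating gene families shared between related
    processes).  Within-member probabilities are drawn from a concentrated
    Dirichlet so thresholded extraction is exercised nontrivially.
    """
    rng = np.random.default_rng(seed)
    lo, hi = module_size_range
    if not 1 <= lo <= hi:
        raise ValueError("invalid module size range")
    sizes = rng.integers(lo, hi + 1, size=k_true)
    needed = int(sizes.sum()) - overlap_terms * max(0, k_true - 1)
    if needed > vocab_size:
        raise ValueError(
            f"{k_true} modules of sizes {sizes.tolist()} do not fit in a "
            f"vocabulary of {vocab_size} terms"
        )
    width = max(5, len(str(vocab_size)))
    vocabulary = [f"OG{i:0{width}d}" for i in range(vocab_size)]
    pool = list(rng.permutation(vocab_size))
    members: list[list[int]] = []
    for i in range(k_true):
        size = int(sizes[i])
        fresh = size
        shared: list[int] = []
        if overlap_terms and i > 0:
            shared = members[i - 1][:overlap_terms]
            fresh = size - len(shared)
        take, pool = pool[:fresh], pool[fresh:]
        members.append(shared + take)

    phi = np.zeros((k_true, vocab_size))
    for i, mem in enumerate(members):
        within = rng.dirichlet(np.full(len(mem), member_concentration))
        phi[i, mem] = within * (1.0 - background_mass)
        if background_mass > 0:
            rest = np.setdiff1d(np.arange(vocab_size), mem)
            phi[i, rest] = background_mass / len(rest)
    return PlantedModel(
        vocabulary=vocabulary,
        module_members=[
            frozenset(vocabulary[j] for j in mem) for mem in members
        ],
        phi_star=phi,
    )


def generate_corpus(
    model: PlantedModel,
    n_documents: int,
    doc_length_mean: float = 1000.0,
    mixture_mode: str = "sparse",
    alpha_true: float = 0.5,
    max_active_modules: int = 3,
    seed: int = 0,
) -> tuple[AnnotationCorpus, dict]:
    """Sample a corpus from the planted model.

    ``mixture_mode="dirichlet"`` draws each document's module weights from a
    symmetric Dirichlet(alpha_true); ``"sparse"`` activates 1 to
    ``max_active_modules`` modules per document with Dirichlet(1) weights,
    the regime where a genome is shaped by one or a few processes.  Document
    lengths are Poisson(doc_length_mean), clipped to at least 1.

    Returns the corpus plus a truth dict with ``theta_star`` (D x k_true)
    and ``z_star`` (per-document true module assignment of each token).
    """
    if n_documents < 1:
        raise ValueError("n_documents must be >= 1")
    if mixture_mode not in ("dirichlet", "sparse"):
        raise ValueError(f"unknown mixture_mode: {mixture_mode!r}")
    rng = np.random.default_rng(seed)
    k = model.k_true
    theta_star = np.zeros((n_documents, k))
    docs = [f"genome{j:04d}" for j in range(n_documents)]
    doc_tokens: list[list[str]] = []
    z_star: list[np.ndarray] = []
    vocab_arr = np.array(model.vocabulary)
    for j in range(n_documents):
        if mixture_mode == "dirichlet":
            theta = rng.dirichlet(np.full(k, alpha_true))
        else:
            n_active = int(rng.integers(1, min(max_active_modules, k) + 1))
            active = rng.choice(k, size=n_active, replace=False)
            theta = np.zeros(k)
            theta[active] = rng.dirichlet(np.ones(n_active))
        theta_star[j] = theta
        length = max(1, int(rng.poisson(doc_length_mean)))
        zs = rng.choice(k, size=length, p=theta)
        words = np.empty(length, dtype=vocab_arr.dtype)
        for t in range(k):
            mask = zs == t
            if mask.any():
                words[mask] = vocab_arr[
                    rng.choice(len(vocab_arr), size=int(mask.sum()), p=model.phi_star[t])
                ]
        doc_tokens.append(words.tolist())
        z_star.append(zs)
    corpus = AnnotationCorpus(
        documents=docs, doc_tokens=doc_tokens, vocabulary=list(model.vocabulary)
    )
    return corpus, {"theta_star": theta_star, "z_star": z_star}


def generate_reference(
    model: PlantedModel,
    tpr: float = 0.6,
    fpr: float = 1e-4,
    cooc_tpr: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit a synthetic channel-score table matched to the planted modules.

    Each within-module pair is emitted with a high-confidence decomposition
    (signal in the "database" and "neighborhood" channels) with probability
    ``tpr``; cross-module pairs are emitted at rate ``fpr``.  The
    "cooccurence" channel is drawn independently (rate ``cooc_tpr`` among
    within-module pairs) so that baseline-vs-module comparisons are
    meaningful.
    """
    if not (0 <= tpr <= 1 and 0 <= fpr <= 1):
        raise ValueError("tpr and fpr must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []

    def emit(a: str, b: str, linked: bool) -> None:
        row = {"term_a": a, "term_b": b}
        for c in CHANNELS:
            row[c] = 0.0
        if linked:
            row["database"] = float(rng.uniform(0.85, 0.98))
            row["neighborhood"] = float(rng.uniform(0.6, 0.9))
            if rng.random() < cooc_tpr:
                row["cooccurence"] = float(rng.uniform(0.4, 0.9))
        else:
            row["textmining"] = float(rng.uniform(0.15, 0.5))
        rows.append(row)

    within: set[frozenset[str]] = set()
    for mem in model.module_members:
        for a, b in combinations(sorted(mem), 2):
            within.add(frozenset((a, b)))
    for pair in sorted(within, key=lambda p: tuple(sorted(p))):
        a, b = sorted(pair)
        if rng.random() < tpr:
            emit(a, b, linked=True)
        elif rng.random() < 0.5:
            # weak-evidence distractor row: stays below the confidence cut
            emit(a, b, linked=False)
    if fpr > 0:
        v = len(model.vocabulary)
        n_cross_target = int(round(fpr * (v * (v - 1) // 2)))
        emitted = 0
        while emitted < n_cross_target:
            i, j = rng.integers(0, v, size=2)
            if i == j:
                continue
            pair = frozenset((model.vocabulary[i], model.vocabulary[j]))
            if pair in within:
                continue
            a, b = sorted(pair)
            emit(a, b, linked=True)
            emitted += 1
    return pd.DataFrame(rows, columns=["term_a", "term_b", *CHANNELS])


def recovery_score(
    planted: Sequence[frozenset[str]] | PlantedModel,
    recovered: Sequence[PFModule],
) -> tuple[float, list[tuple[int, int, float]]]:
    """Greedy best-match Jaccard between planted member sets and modules.

    Matches are accepted in descending Jaccard order, one-to-one; the score
    is the mean over planted modules with unmatched planted sets scoring 0.
    Returns (mean score, list of (planted_idx, recovered_idx, jaccard)).
    """
    if isinstance(planted, PlantedModel):
        planted_sets = list(planted.module_members)
    else:
        planted_sets = [frozenset(s) for s in planted]
    rec_sets = [m.term_set for m in recovered]
    cand = []
    for i, p in enumerate(planted_sets):
        for j, r in enumerate(rec_sets):
            union = len(p | r)
            jac = len(p & r) / union if union else 0.0
            cand.append((jac, i, j))
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_p: set[int] = set()
    used_r: set[int] = set()
    matches: list[tuple[int, int, float]] = []
    for jac, i, j in cand:
        if i in used_p or j in used_r or jac <= 0.0:
            continue
        used_p.add(i)
        used_r.add(j)
        matches.append((i, j, jac))
    total = sum(j for _, _, j in matches)
    mean = total / len(planted_sets) if planted_sets else 0.0
    return mean, matches
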