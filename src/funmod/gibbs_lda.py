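"""Collapsed Gibbs sampling for latent Dirichlet allocation.

The model: each of k topics t_i is a multinomial over the vocabulary V with a
symmetric Dirichlet(beta) prior; each document d_j mixes topics with weights
drawn from a symmetric Dirichlet(alpha) prior.  With the multinomial
parameters integrated out, a single token's topic is resampled from

    P(z = t | rest) ∝ (n_wt[w,t] + beta) / (n_t[t] + |V| beta) * (n_td[t,d] + alpha)

where the counts exclude the token being resampled.  Tokens are scanned in
document order then token order, so a run is exactly reproducible from its
seed.  Point estimates of the topic-term distributions phi and document-topic
weights theta are taken from the final sample by default:

    phi[t,w]   = (n_wt[w,t] + beta) / (n_t[t] + |V| beta)
    theta[d,t] = (n_td[t,d] + alpha) / (len(d) + k alpha)

The inner sweep is JIT-compiled with numba when available; a NumPy/Python
fallback consumes the same pre-drawn uniform variates, so both paths produce
bitwise-identical chains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import gammaln

from funmod.corpus_io import AnnotationCorpus

logger = logging.getLogger(__name__)

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@dataclass(frozen=True)
class LDAConfig:
    """Hyperparameters and run controls for one Gibbs-LDA fit.

    Defaults follow the large-corpus setting used for prokaryotic genome
    annotations: k=200 topics, alpha=0.5, beta=0.01, 2,500 full sweeps.
    ``average_last`` > 0 averages phi/theta over that many trailing sweeps
    instead of using the final sample only.
    """

    k: int = 200
    alpha: float = 0.5
    beta: float = 0.01
    n_iterations: int = 2500
    seed: int = 0
    average_last: int = 0
    log_every: int = 100

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class TopicModel:
    """Sampler state: token-topic assignments plus sufficient-count matrices.

    ``n_wt`` is term-by-topic (|V| x k), ``n_td`` topic-by-document (k x D),
    ``n_t`` the per-topic token totals.  The counts are always exactly the
    tallies of ``z``.
    """

    config: LDAConfig
    vocabulary: list[str]
    documents: list[str]
    doc_ids: np.ndarray
    word_ids: np.ndarray
    z: np.ndarray
    n_wt: np.ndarray
    n_td: np.ndarray
    n_t: np.ndarray
    doc_lengths: np.ndarray
    rng: np.random.Generator = field(repr=False, default=None)  # type: ignore[assignment]
    log_joint_trace: list[tuple[int, float]] = field(default_factory=list)
    _phi_acc: Optional[np.ndarray] = field(default=None, repr=False)
    _theta_acc: Optional[np.ndarray] = field(default=None, repr=False)
    _acc_n: int = 0

    @property
    def n_tokens(self) -> int:
        return int(self.z.shape[0])

    def check_invariants(self) -> None:
        """Assert count matrices are exact tallies of z (debug aid)."""
        k = self.config.k
        V = len(self.vocabulary)
        D = len(self.documents)
        n_wt = np.zeros((V, k), dtype=np.int64)
        n_td = np.zeros((k, D), dtype=np.int64)
        np.add.at(n_wt, (self.word_ids, self.z), 1)
        np.add.at(n_td, (self.z, self.doc_ids), 1)
        assert np.array_equal(n_wt, self.n_wt), "n_wt inconsistent with z"
        assert np.array_equal(n_td, self.n_td), "n_td inconsistent with z"
        assert np.array_equal(n_wt.sum(axis=0), self.n_t), "n_t inconsistent"
        assert np.array_equal(self.n_td.sum(axis=0), self.doc_lengths)


@dataclass(frozen=True)
class TopicDistributions:
    """Point estimates phi (k x |V|) and theta (D x k); rows sum to one."""

    phi: np.ndarray
    theta: np.ndarray
    vocabulary: list[str]
    documents: list[str]

    def __post_init__(self) -> None:
        if not np.allclose(self.phi.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("phi rows must sum to 1")
        if not np.allclose(self.theta.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("theta rows must sum to 1")


@njit(cache=True)
def _sweep_numba(doc_ids, word_ids, z, n_wt, n_td, n_t, alpha, beta, uniforms):
    V, k = n_wt.shape
    vbeta = V * beta
    cum = np.empty(k, dtype=np.float64)
    for i in range(z.shape[0]):
        w = word_ids[i]
        d = doc_ids[i]
        t_old = z[i]
        n_wt[w, t_old] -= 1
        n_td[t_old, d] -= 1
        n_t[t_old] -= 1
        total = 0.0
        for t in range(k):
            total += (
                (n_wt[w, t] + beta) / (n_t[t] + vbeta) * (n_td[t, d] + alpha)
            )
            cum[t] = total
        r = uniforms[i] * total
        t_new = 0
        while cum[t_new] < r:
            t_new += 1
        z[i] = t_new
        n_wt[w, t_new] += 1
        n_td[t_new, d] += 1
        n_t[t_new] += 1


def _sweep_python(doc_ids, word_ids, z, n_wt, n_td, n_t, alpha, beta, uniforms):
    # Mirrors _sweep_numba exactly (same uniforms -> same chain).
    V, k = n_wt.shape
    vbeta = V * beta
    for i in range(z.shape[0]):
        w = word_ids[i]
        d = doc_ids[i]
        t_old = z[i]
        n_wt[w, t_old] -= 1
        n_td[t_old, d] -= 1
        n_t[t_old] -= 1
        p = (n_wt[w, :] + beta) / (n_t + vbeta) * (n_td[:, d] + alpha)
        cum = np.cumsum(p)
        t_new = int(np.searchsorted(cum, uniforms[i] * cum[-1], side="left"))
        if t_new >= k:  # guard against rounding at the top edge
            t_new = k - 1
        z[i] = t_new
        n_wt[w, t_new] += 1
        n_td[t_new, d] += 1
        n_t[t_new] += 1


def initialize(corpus: AnnotationCorpus, config: LDAConfig) -> TopicModel:
    """Assign every token a uniformly random topic and tally the counts."""
    if not corpus.vocabulary:
        raise ValueError("corpus vocabulary is empty")
    doc_ids, word_ids = corpus.encode()
    rng = np.random.default_rng(config.seed)
    n = doc_ids.shape[0]
    z = rng.integers(0, config.k, size=n, dtype=np.int32)
    V = len(corpus.vocabulary)
    D = corpus.n_documents
    n_wt = np.zeros((V, config.k), dtype=np.int64)
    n_td = np.zeros((config.k, D), dtype=np.int64)
    np.add.at(n_wt, (word_ids, z), 1)
    np.add.at(n_td, (z, doc_ids), 1)
    doc_lengths = np.array([len(t) for t in corpus.doc_tokens], dtype=np.int64)
    return TopicModel(
        config=config,
        vocabulary=list(corpus.vocabulary),
        documents=list(corpus.documents),
        doc_ids=doc_ids,
        word_ids=word_ids,
        z=z,
        n_wt=n_wt,
        n_td=n_td,
        n_t=n_wt.sum(axis=0),
        doc_lengths=doc_lengths,
        rng=rng,
    )


def gibbs_sweep(model: TopicModel) -> TopicModel:
    """Resample every token once, in document-then-position order (in place)."""
    uniforms = model.rng.random(model.n_tokens)
    sweep = _sweep_numba if _HAVE_NUMBA else _sweep_python
    sweep(
        model.doc_ids,
        model.word_ids,
        model.z,
        model.n_wt,
        model.n_td,
        model.n_t,
        model.config.alpha,
        model.config.beta,
        uniforms,
    )
    return model


def log_joint(model: TopicModel) -> float:
    """Collapsed log P(w, z): Dirichlet-multinomial terms per topic and doc."""
    k = model.config.k
    V = len(model.vocabulary)
    a, b = model.config.alpha, model.config.beta
    lp = k * (gammaln(V * b) - V * gammaln(b))
    lp += float(gammaln(model.n_wt + b).sum() - gammaln(model.n_t + V * b).sum())
    D = len(model.documents)
    lp += D * (gammaln(k * a) - k * gammaln(a))
    lp += float(
        gammaln(model.n_td + a).sum() - gammaln(model.doc_lengths + k * a).sum()
    )
    return lp


def fit(corpus: AnnotationCorpus, config: LDAConfig) -> TopicModel:
    """Run ``config.n_iterations`` full Gibbs sweeps from a seeded start.

    The collapsed log joint is recorded every ``log_every`` sweeps for
    convergence monitoring only; the iteration count is fixed, never adaptive.
    """
    model = initialize(corpus, config)
    avg_from = config.n_iterations - config.average_last
    for it in range(1, config.n_iterations + 1):
        gibbs_sweep(model)
        if config.log_every and it % config.log_every == 0:
            lj = log_joint(model)
            model.log_joint_trace.append((it, lj))
            logger.info("sweep %d/%d log-joint %.2f", it, config.n_iterations, lj)
        if config.average_last and it > avg_from:
            _accumulate(model)
    return model


def _accumulate(model: TopicModel) -> None:
    phi, theta = _point_estimates(model)
    if model._phi_acc is None:
        model._phi_acc = phi
        model._theta_acc = theta
    else:
        model._phi_acc += phi
        model._theta_acc += theta
    model._acc_n += 1


def _point_estimates(model: TopicModel) -> tuple[np.ndarray, np.ndarray]:
    b, a = model.config.beta, model.config.alpha
    V = len(model.vocabulary)
    k = model.config.k
    phi = (model.n_wt.T + b) / (model.n_t[:, None] + V * b)
    theta = (model.n_td.T + a) / (model.doc_lengths[:, None] + k * a)
    return phi, theta


def estimate_distributions(model: TopicModel) -> TopicDistributions:
    """Smoothed phi/theta from the final sample (or the trailing average)."""
    if model._acc_n:
        phi = model._phi_acc / model._acc_n
        theta = model._theta_acc / model._acc_n
    else:
        phi, theta = _point_estimates(model)
    return TopicDistributions(
        phi=phi,
        theta=theta,
        vocabulary=list(model.vocabulary),
        documents=list(model.documents),
    )


def document_word_distribution(dists: TopicDistributions, j: int) -> np.ndarray:
    """Mixture P(w|d_j) = sum_i P(w|t_i) P(t_i|d_j) for document j."""
    if not 0 <= j < dists.theta.shape[0]:
        raise IndexError(f"document index {j} out of range")
    return dists.theta[j] @ dists.phi
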