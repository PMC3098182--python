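"""Reference-network evaluation of PF-modules.

The reference set U is built from a STRING-style multi-channel score table:
per-channel reliabilities are recombined without the co-occurrence channel
(prior-corrected noisy-OR), and unordered term pairs with both members in
the model vocabulary and a recombined score of at least 0.7 form the
high-confidence evaluation graph.  Excluding the co-occurrence channel keeps
the evaluation independent of the very signal the topic model exploits.

For each module: its pairs found in U are *verified pairwise functional
couplings* (pwf); unmatched pairs whose two members share a third module
member with pwf couplings to both are *verified first-order transitive
couplings* (trf); *coverage* is the fraction of the module's terms inside
the largest connected component of the pwf edge subgraph.  Chance agreement
is quantified with the hypergeometric distribution over the universe D of
all vocabulary pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from funmod.module_extraction import PFModule, module_pairs

#: STRING evidence channels, in table-column order.  "cooccurence" is the
#: spelling used in the upstream data dialect.
CHANNELS = (
    "neighborhood",
    "fusion",
    "cooccurence",
    "coexpression",
    "experimental",
    "database",
    "textmining",
)

#: Conventional prior probability of a random pair being functionally linked,
#: used by the prior-corrected noisy-OR combination.
DEFAULT_PRIOR = 0.063

Pair = frozenset


@dataclass(frozen=True)
class ReferenceNetwork:
    """High-confidence unordered term pairs restricted to a vocabulary."""

    pairs: frozenset[frozenset[str]]
    vocabulary: frozenset[str]
    scores: dict[frozenset[str], float] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_universe(self) -> int:
        v = len(self.vocabulary)
        return v * (v - 1) // 2

    def __contains__(self, pair: frozenset[str]) -> bool:
        return pair in self.pairs


@dataclass(frozen=True)
class ModuleEvaluation:
    """Per-module verification and significance summary."""

    topic_id: int
    l: int  # noqa: E741 - module size symbol
    m: int
    pwf: frozenset[frozenset[str]]
    trf: frozenset[frozenset[str]]
    coverage: float
    n_components: int
    p_hit: float
    expected_hits: float
    p_mult_hit: float


def read_score_table(path: str | Path) -> pd.DataFrame:
    """Read a multi-channel pair-score table (TSV, optionally gzipped).

    Expected columns: ``term_a term_b`` followed by the seven channels and an
    optional ``combined_score``.  "cooccurrence" is accepted as an alias for
    the data dialect's "cooccurence".  Integer scores above 1 are taken as
    milli-scores (0-999) and divided by 1000.
    """
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={"cooccurrence": "cooccurence"})
    missing = [c for c in ("term_a", "term_b") if c not in df.columns]
    if missing:
        raise ValueError(f"score table missing columns: {missing}")
    for col in df.columns:
        if col in ("term_a", "term_b"):
            continue
        vals = df[col].astype(float)
        if (vals > 1).any():
            vals = vals / 1000.0
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"channel {col!r} has scores outside [0, 1]")
        df[col] = vals
    return df


def combine_channel_scores(
    scores: Mapping[str, float],
    excluded_channels: Iterable[str] = ("cooccurence",),
    prior: float = DEFAULT_PRIOR,
) -> float:
    """Prior-corrected noisy-OR combination of channel reliabilities.

    Each included channel score is first stripped of the prior,
    s' = max(0, (s - prior) / (1 - prior)); the corrected scores are combined
    as S' = 1 - prod(1 - s'), and the prior is added back:
    S = S' (1 - prior) + prior, or 0 when no channel survives correction.
    """
    if not 0 <= prior < 1:
        raise ValueError("prior must lie in [0, 1)")
    excluded = set(excluded_channels)
    corrected = []
    for name, s in scores.items():
        if name in excluded or name == "combined_score":
            continue
        corrected.append(max(0.0, (s - prior) / (1.0 - prior)))
    if not any(c > 0 for c in corrected):
        return 0.0
    s_prime = 1.0 - float(np.prod([1.0 - c for c in corrected]))
    return s_prime * (1.0 - prior) + prior


def build_reference(
    table: pd.DataFrame,
    vocab: Iterable[str],
    min_combined: float = 0.7,
    inclusion_floor: float = 0.15,
    excluded_channels: Iterable[str] = ("cooccurence",),
    prior: float = DEFAULT_PRIOR,
    use_precomputed: bool = False,
) -> ReferenceNetwork:
    """Build the high-confidence reference network U.

    Combined scores are recomputed without the excluded channels (unless
    ``use_precomputed`` and a ``combined_score`` column is present); pairs
    below ``inclusion_floor`` are discarded, then pairs are kept when both
    terms are in ``vocab`` and the score is at least ``min_combined``
    (inclusive).  Duplicate unordered pairs keep their maximum score.
    """
    vocab_set = frozenset(vocab)
    channel_cols = [c for c in CHANNELS if c in table.columns]
    scores: dict[frozenset[str], float] = {}
    for row in table.itertuples(index=False):
        rowd = row._asdict()
        a, b = str(rowd["term_a"]), str(rowd["term_b"])
        if a == b:
            continue
        if use_precomputed and "combined_score" in rowd:
            s = float(rowd["combined_score"])
        else:
            s = combine_channel_scores(
                {c: float(rowd[c]) for c in channel_cols},
                excluded_channels=excluded_channels,
                prior=prior,
            )
        if s < inclusion_floor:
            continue
        if a not in vocab_set or b not in vocab_set:
            continue
        key = frozenset((a, b))
        if s >= scores.get(key, -1.0):
            scores[key] = s
    kept = {p: s for p, s in scores.items() if s >= min_combined}
    return ReferenceNetwork(
        pairs=frozenset(kept), vocabulary=vocab_set, scores=kept
    )


def verify_pwf(
    module: PFModule, ref: ReferenceNetwork
) -> tuple[frozenset[frozenset[str]], float]:
    """Module pairs found directly in the reference, and their fraction of m."""
    pairs = module_pairs(module)
    hits = frozenset(p for p in pairs if p in ref.pairs)
    frac = len(hits) / len(pairs) if pairs else 0.0
    return hits, frac


def verify_trf(
    module: PFModule,
    ref: ReferenceNetwork,
    pwf: frozenset[frozenset[str]],
) -> frozenset[frozenset[str]]:
    """First-order transitive couplings among the module's unmatched pairs.

    A non-verified pair (a, b) is transitively verified when some third
    module member c has verified pairwise couplings to both a and b.
    """
    adjacency: dict[str, set[str]] = {}
    for p in pwf:
        a, b = tuple(p)
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)
    out = set()
    for pair in module_pairs(module) - set(pwf):
        a, b = tuple(pair)
        if adjacency.get(a, set()) & adjacency.get(b, set()):
            out.add(pair)
    return frozenset(out)


def coverage(
    module: PFModule, pwf: Iterable[frozenset[str]]
) -> tuple[float, int]:
    """Largest-component fraction and component count of the pwf subgraph.

    Components are taken over vertices incident to at least one verified
    edge; isolated module terms are not counted as components.  A module
    with no verified edges has coverage 0 and 0 components.
    """
    g = nx.Graph()
    for p in pwf:
        a, b = tuple(p)
        g.add_edge(a, b)
    if g.number_of_edges() == 0:
        return 0.0, 0
    comps = list(nx.connected_components(g))
    largest = max(len(c) for c in comps)
    return largest / module.l, len(comps)


def hypergeom_significance(
    m: int, h: int, n_reference: int, n_universe: int
) -> tuple[float, float, float]:
    """Chance-match statistics for h verified hits among m tested pairs.

    Returns (P_hit, E[h], P_mult_hit): the per-pair chance-match probability
    |U|/|D|, the expected hit count m|U|/|D|, and the hypergeometric
    upper-tail probability P(X >= h) of drawing at least h reference pairs
    in m draws without replacement from the |D| vocabulary pairs.
    """
    if h > m:
        raise ValueError("observed hits cannot exceed tested pairs")
    if m > n_universe:
        raise ValueError("tested pairs cannot exceed the pair universe")
    p_hit = n_reference / n_universe
    expected = m * p_hit
    # survival function at h-1 gives P(X >= h); exact 1.0 for h = 0
    p_mult = float(hypergeom.sf(h - 1, n_universe, n_reference, m))
    return p_hit, expected, p_mult


def evaluate_module(module: PFModule, ref: ReferenceNetwork) -> ModuleEvaluation:
    """Full per-module evaluation: pwf, trf, coverage, significance."""
    pairs = module_pairs(module)
    pwf, _ = verify_pwf(module, ref)
    trf = verify_trf(module, ref, pwf)
    cov, n_comp = coverage(module, pwf)
    p_hit, expected, p_mult = hypergeom_significance(
        len(pairs), len(pwf), ref.n_pairs, ref.n_universe
    )
    return ModuleEvaluation(
        topic_id=module.topic_id,
        l=module.l,
        m=len(pairs),
        pwf=pwf,
        trf=trf,
        coverage=cov,
        n_components=n_comp,
        p_hit=p_hit,
        expected_hits=expected,
        p_mult_hit=p_mult,
    )


def cooccurrence_baseline(
    table: pd.DataFrame,
    vocab: Iterable[str],
    threshold: float = 0.4,
) -> frozenset[frozenset[str]]:
    """Pairwise co-occurrence predictions: channel score >= threshold.

    The 0.4 default is the lower bound of the medium-confidence score range.
    """
    vocab_set = frozenset(vocab)
    if "cooccurence" not in table.columns:
        raise ValueError("score table has no cooccurence channel")
    out = set()
    for a, b, s in zip(
        table["term_a"], table["term_b"], table["cooccurence"].astype(float)
    ):
        a, b = str(a), str(b)
        if a != b and s >= threshold and a in vocab_set and b in vocab_set:
            out.add(frozenset((a, b)))
    return frozenset(out)


def compare_methods(
    modules: Sequence[PFModule],
    baseline: frozenset[frozenset[str]],
    ref: ReferenceNetwork,
) -> dict:
    """Venn accounting of module-derived pairs vs the co-occurrence baseline.

    Reports the union of module pairs, the verified subsets of each method,
    three-way overlap counts against the reference, per-method recall
    |verified ∩ method| / |U|, and the number of distinct terms appearing in
    the pairs of each Venn section.
    """
    module_set: set[frozenset[str]] = set()
    for mod in modules:
        module_set |= module_pairs(mod)
    mod_pairs = frozenset(module_set)
    u = ref.pairs
    verified_mod = mod_pairs & u
    verified_base = baseline & u

    sections = {
        "modules_only": mod_pairs - baseline,
        "baseline_only": baseline - mod_pairs,
        "both": mod_pairs & baseline,
    }

    def n_terms(pairs: Iterable[frozenset[str]]) -> int:
        return len({t for p in pairs for t in p})

    return {
        "n_module_pairs": len(mod_pairs),
        "n_baseline_pairs": len(baseline),
        "n_reference_pairs": len(u),
        "n_verified_module_pairs": len(verified_mod),
        "n_verified_baseline_pairs": len(verified_base),
        "n_verified_both": len(verified_mod & verified_base),
        "n_verified_modules_only": len(verified_mod - verified_base),
        "n_verified_baseline_only": len(verified_base - verified_mod),
        "recall_modules": len(verified_mod) / len(u) if u else 0.0,
        "recall_baseline": len(verified_base) / len(u) if u else 0.0,
        "venn_counts": {k: len(v) for k, v in sections.items()},
        "venn_term_counts": {k: n_terms(v) for k, v in sections.items()},
        "module_pairs": mod_pairs,
        "baseline_pairs": baseline,
        "verified_module_pairs": verified_mod,
        "verified_baseline_pairs": verified_base,
    }


def write_reference(ref: ReferenceNetwork, path: str | Path) -> None:
    """Export the reference as a two-term TSV with combined scores."""
    rows = [
        {"term_a": a, "term_b": b, "combined_score": ref.scores.get(p, float("nan"))}
        for p in sorted(ref.pairs, key=lambda p: tuple(sorted(p)))
        for a, b in [tuple(sorted(p))]
    ]
    pd.DataFrame(rows, columns=["term_a", "term_b", "combined_score"]).to_csv(
        path, sep="\t", index=False
    )


def read_reference(path: str | Path, vocab: Iterable[str]) -> ReferenceNetwork:
    """Read a previously exported reference TSV (no re-filtering applied)."""
    df = pd.read_csv(path, sep="\t")
    scores = {
        frozenset((str(a), str(b))): float(s)
        for a, b, s in zip(df["term_a"], df["term_b"], df["combined_score"])
    }
    return ReferenceNetwork(
        pairs=frozenset(scores), vocabulary=frozenset(vocab), scores=scores
    )
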