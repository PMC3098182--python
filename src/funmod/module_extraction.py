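"""Turning topic distributions into potential functional modules (PF-modules).

A PF-module is the set of vocabulary terms whose probability under one topic
reaches the extraction threshold C (default 0.01).  Because topics are
global distributions, modules may overlap in term content — the soft
clustering that lets one gene family belong to several processes.  Profiling
helpers relate modules to COG-style functional categories and to KEGG
pathways via KO identifiers.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Optional

from funmod.gibbs_lda import TopicDistributions


@dataclass(frozen=True)
class PFModule:
    """One topic's thresholded term set with per-term probabilities P(w|t)."""

    topic_id: int
    run_id: int
    terms: dict[str, float]

    @property
    def l(self) -> int:  # noqa: E743 - field-standard symbol for module size
        return len(self.terms)

    @property
    def term_set(self) -> frozenset[str]:
        return frozenset(self.terms)


@dataclass(frozen=True)
class ModuleProfile:
    topic_id: int
    modal_category: str
    modal_fraction: float


def extract_modules(
    dists: TopicDistributions,
    C: float = 0.01,
    run_id: int = 0,
    strict: bool = False,
) -> list[PFModule]:
    """One candidate module per topic: terms with P(w|t) >= C.

    Empty candidates (no term reaching C) are dropped; modules are ordered by
    topic index.  The comparison is inclusive by default; ``strict=True``
    switches to a strictly-greater comparison.
    """
    if not 0 < C < 1:
        raise ValueError("threshold C must lie in (0, 1)")
    modules = []
    for t in range(dists.phi.shape[0]):
        row = dists.phi[t]
        if strict:
            hits = {w: float(p) for w, p in zip(dists.vocabulary, row) if p > C}
        else:
            hits = {w: float(p) for w, p in zip(dists.vocabulary, row) if p >= C}
        if hits:
            modules.append(PFModule(topic_id=t, run_id=run_id, terms=hits))
    return modules


def module_pairs(module: PFModule) -> set[frozenset[str]]:
    """All l(l-1)/2 unordered term pairs of a module (empty when l < 2)."""
    return {frozenset(p) for p in combinations(sorted(module.terms), 2)}


def _categories_of(term: str, term_category_map: Mapping[str, object]) -> list[str]:
    # COG convention writes multi-category assignments as letter strings
    # ("TN" = signal transduction + cell motility); iterables are taken as-is.
    cats = term_category_map.get(term)
    if cats is None:
        return []
    if isinstance(cats, str):
        return list(cats)
    return [str(c) for c in cats]


def category_profile(
    module: PFModule,
    term_category_map: Mapping[str, object],
    min_size: int = 7,
) -> Optional[ModuleProfile]:
    """Most frequent functional category of a module's terms.

    A term carrying multiple categories contributes one count to each; the
    fraction denominator stays at module size l, so fractions of different
    categories can sum above one.  Unmapped terms contribute no counts but
    remain in the denominator.  Modules smaller than ``min_size`` are
    skipped (returns None).  Ties break lexicographically on the label.
    """
    if module.l < min_size:
        return None
    counts: Counter[str] = Counter()
    for term in module.terms:
        counts.update(_categories_of(term, term_category_map))
    if not counts:
        return None
    top = max(counts.values())
    modal = min(label for label, n in counts.items() if n == top)
    return ModuleProfile(
        topic_id=module.topic_id,
        modal_category=modal,
        modal_fraction=top / module.l,
    )


def pathway_profile(
    modules: Iterable[PFModule],
    term_ko_map: Mapping[str, object],
    ko_pathway_map: Mapping[str, Iterable[str]],
    min_hits: int = 6,
) -> dict[int, dict[str, int]]:
    """Pathways matched by each module through KO identifiers.

    A hit is a distinct member KO term present in a pathway (a KO matched by
    two module terms counts once).  Only pathways with at least ``min_hits``
    hits are reported.  Both maps may be partial; terms without a KO mapping
    contribute nothing.
    """
    out: dict[int, dict[str, int]] = {}
    for module in modules:
        kos: set[str] = set()
        for term in module.terms:
            mapped = term_ko_map.get(term)
            if mapped is None:
                continue
            if isinstance(mapped, str):
                kos.add(mapped)
            else:
                kos.update(str(k) for k in mapped)
        pathway_kos: dict[str, set[str]] = {}
        for ko in kos:
            for pw in ko_pathway_map.get(ko, ()):  # type: ignore[arg-type]
                pathway_kos.setdefault(pw, set()).add(ko)
        hits = {
            pw: len(members)
            for pw, members in sorted(pathway_kos.items())
            if len(members) >= min_hits
        }
        if hits:
            out[module.topic_id] = hits
    return out
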