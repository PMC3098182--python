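"""Reading, validating, filtering and summarizing genome-annotation corpora.

A corpus is a collection of genome "documents", each a multiset of
functional-descriptor tokens (one token per annotated gene).  Gene order is
deliberately not represented: the model treats each genome as a bag of
descriptors.  Two tab-separated layouts are supported:

* ``wide`` — one row per genome: ``genome_id<TAB>term term term ...``
* ``long`` — one row per gene: ``genome_id<TAB>term``

Files may be plain text or gzip-compressed (detected by ``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class AnnotationCorpus:
    """Genome documents as bags of functional-descriptor tokens.

    Attributes
    ----------
    documents:
        Genome identifiers in first-appearance order.
    doc_tokens:
        Per-document token lists (term strings, multiplicities preserved:
        a term annotated on g genes of one genome appears g times).
    vocabulary:
        Distinct terms in lexicographic order; fixed after construction so
        matrix column indices are reproducible.
    """

    documents: list[str]
    doc_tokens: list[list[str]]
    vocabulary: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.documents) < 1:
            raise ValueError("corpus must contain at least one document")
        if len(self.documents) != len(self.doc_tokens):
            raise ValueError("documents and doc_tokens length mismatch")
        if not self.vocabulary:
            self.vocabulary = sorted({t for toks in self.doc_tokens for t in toks})
        vocab_set = set(self.vocabulary)
        for toks in self.doc_tokens:
            for t in toks:
                if t not in vocab_set:
                    raise ValueError(f"token term {t!r} not in vocabulary")

    @property
    def n_documents(self) -> int:
        return len(self.documents)

    @property
    def n_tokens(self) -> int:
        return sum(len(t) for t in self.doc_tokens)

    @property
    def doc_freq(self) -> dict[str, int]:
        """Number of documents containing at least one token of each term."""
        df: dict[str, int] = {}
        for toks in self.doc_tokens:
            for term in set(toks):
                df[term] = df.get(term, 0) + 1
        return df

    def term_index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.vocabulary)}

    def encode(self) -> tuple[np.ndarray, np.ndarray]:
        """Flatten tokens to parallel ``(doc_ids, word_ids)`` int32 arrays.

        Token order is document order then within-document order, which is
        also the scan order of the Gibbs sampler.
        """
        idx = self.term_index()
        doc_ids = np.empty(self.n_tokens, dtype=np.int32)
        word_ids = np.empty(self.n_tokens, dtype=np.int32)
        pos = 0
        for j, toks in enumerate(self.doc_tokens):
            for t in toks:
                doc_ids[pos] = j
                word_ids[pos] = idx[t]
                pos += 1
        return doc_ids, word_ids

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationCorpus):
            return NotImplemented
        return (
            self.documents == other.documents
            and self.vocabulary == other.vocabulary
            and [sorted(t) for t in self.doc_tokens]
            == [sorted(t) for t in other.doc_tokens]
        )


@dataclass(frozen=True)
class CorpusStats:
    n_documents: int
    n_vocab: int
    n_tokens: int
    doc_length_min: int
    doc_length_median: float
    doc_length_max: int


def corpus_stats(corpus: AnnotationCorpus) -> CorpusStats:
    lengths = [len(t) for t in corpus.doc_tokens]
    return CorpusStats(
        n_documents=corpus.n_documents,
        n_vocab=len(corpus.vocabulary),
        n_tokens=corpus.n_tokens,
        doc_length_min=min(lengths),
        doc_length_median=float(np.median(lengths)),
        doc_length_max=max(lengths),
    )


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding="utf-8")  # type: ignore[return-value]
    return open(path, mode, encoding="utf-8")


def _iter_rows(handle: IO[str]) -> Iterator[tuple[int, list[str]]]:
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        yield lineno, line.split("\t")


def read_corpus(path: str | Path, format: str = "wide") -> AnnotationCorpus:
    """Read a corpus from a TSV file.

    Parameters
    ----------
    path:
        TSV file, optionally gzip-compressed.
    format:
        ``"wide"`` (genome_id TAB space-separated term list, one row per
        genome) or ``"long"`` (genome_id TAB term, one row per gene).

    Documents appear in first-appearance order; the vocabulary is sorted
    lexicographically.  Duplicate (genome, term) rows in long format become
    multiple tokens.
    """
    if format not in ("wide", "long"):
        raise ValueError(f"unknown corpus format: {format!r}")
    docs: list[str] = []
    tokens: dict[str, list[str]] = {}
    with _open_text(path) as fh:
        for lineno, fields in _iter_rows(fh):
            if len(fields) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns, "
                    f"got {len(fields)}"
                )
            genome, payload = fields
            if genome not in tokens:
                docs.append(genome)
                tokens[genome] = []
            if format == "wide":
                tokens[genome].extend(payload.split())
            else:
                if not payload.strip():
                    raise ValueError(f"{path}: line {lineno}: empty term field")
                tokens[genome].append(payload.strip())
    if not docs:
        raise ValueError(f"{path}: empty corpus file")
    return AnnotationCorpus(documents=docs, doc_tokens=[tokens[g] for g in docs])


def write_corpus(
    corpus: AnnotationCorpus, path: str | Path, format: str = "wide"
) -> None:
    """Write a corpus back to TSV; ``read_corpus`` of the output round-trips."""
    if format not in ("wide", "long"):
        raise ValueError(f"unknown corpus format: {format!r}")
    with _open_text(path, "wt") as fh:
        for genome, toks in zip(corpus.documents, corpus.doc_tokens):
            if format == "wide":
                fh.write(f"{genome}\t{' '.join(toks)}\n")
            else:
                if not toks:
                    logger.warning(
                        "document %s has no tokens; it cannot be represented "
                        "in long format and is dropped on write",
                        genome,
                    )
                for t in toks:
                    fh.write(f"{genome}\t{t}\n")


def filter_vocabulary(
    corpus: AnnotationCorpus, min_doc_freq: int = 10
) -> AnnotationCorpus:
    """Drop terms present in fewer than ``min_doc_freq`` documents.

    Document frequency is presence-based: a term counts once per document
    regardless of its token multiplicity there.  Documents whose tokens are
    all removed stay in the corpus (with zero tokens) and are logged, so
    document indices remain stable.
    """
    if min_doc_freq < 1:
        raise ValueError("min_doc_freq must be >= 1")
    df = corpus.doc_freq
    keep = {t for t in corpus.vocabulary if df.get(t, 0) >= min_doc_freq}
    if not keep:
        raise ValueError(
            f"no term reaches document frequency {min_doc_freq}; "
            "vocabulary would be empty"
        )
    new_tokens = [[t for t in toks if t in keep] for toks in corpus.doc_tokens]
    emptied = [
        g
        for g, old, new in zip(corpus.documents, corpus.doc_tokens, new_tokens)
        if old and not new
    ]
    if emptied:
        logger.warning(
            "%d document(s) left without tokens after vocabulary filtering: %s",
            len(emptied),
            ", ".join(emptied[:10]) + ("..." if len(emptied) > 10 else ""),
        )
    return AnnotationCorpus(
        documents=list(corpus.documents),
        doc_tokens=new_tokens,
        vocabulary=sorted(keep),
    )
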