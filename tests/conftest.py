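import numpy as np
import pytest

from funmod.corpus_io import AnnotationCorpus


@pytest.fixture
def tiny_corpus() -> AnnotationCorpus:
    return AnnotationCorpus(
        documents=["g1", "g2", "g3"],
        doc_tokens=[["A", "A", "B"], ["B", "C"], ["A", "C", "C", "B"]],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240117)


def random_corpus(
    rng: np.random.Generator,
    n_docs: int = 12,
    vocab_size: int = 20,
    max_len: int = 30,
) -> AnnotationCorpus:
    vocab = [f"T{i:02d}" for i in range(vocab_size)]
    docs = []
    for j in range(n_docs):
        length = int(rng.integers(1, max_len))
        docs.append([vocab[i] for i in rng.integers(0, vocab_size, size=length)])
    return AnnotationCorpus(
        documents=[f"g{j}" for j in range(n_docs)], doc_tokens=docs
    )
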