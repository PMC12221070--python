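"""Shared fixtures: small hand-built corpora and random-corpus factories."""

from __future__ import annotations

import numpy as np
import pytest

from sdohminer.corpus import Document, LabeledCorpus, Sentence, Token
from sdohminer.label_schema import DEFAULT_CORE_TYPES


def make_corpus(doc_specs, confidences=False, rng=None):
    """Build a corpus from [[(text, label), ...] per sentence] per document."""
    docs = []
    for di, sentences in enumerate(doc_specs):
        sents = []
        for toks in sentences:
            sents.append(
                Sentence(
                    tuple(
                        Token(
                            text=t,
                            label=lab,
                            confidence=(
                                float(rng.random()) if confidences and rng else None
                            ),
                        )
                        for t, lab in toks
                    )
                )
            )
        docs.append(Document(doc_id=f"d{di}", sentences=tuple(sents)))
    return LabeledCorpus(tuple(docs))


def random_bio_corpus(
    rng: np.random.Generator,
    n_docs: int = 5,
    max_sents: int = 8,
    max_toks: int = 12,
    types: tuple[str, ...] = DEFAULT_CORE_TYPES[:6],
    p_entity: float = 0.3,
    with_confidence: bool = False,
) -> LabeledCorpus:
    """Lightweight random valid-BIO corpus, independent of synthetic_corpus."""
    words = ["w%d" % i for i in range(40)]
    docs = []
    for di in range(n_docs):
        sents = []
        for _ in range(int(rng.integers(1, max_sents + 1))):
            n = int(rng.integers(1, max_toks + 1))
            toks = []
            i = 0
            while i < n:
                if rng.random() < p_entity:
                    t = types[int(rng.integers(len(types)))]
                    span = min(int(rng.integers(1, 4)), n - i)
                    for k in range(span):
                        toks.append(
                            Token(
                                text=words[int(rng.integers(len(words)))],
                                label=("B-" if k == 0 else "I-") + t,
                                confidence=(
                                    float(rng.random()) if with_confidence else None
                                ),
                            )
                        )
                    i += span
                else:
                    toks.append(
                        Token(
                            text=words[int(rng.integers(len(words)))],
                            label="O",
                            confidence=(
                                float(rng.random()) if with_confidence else None
                            ),
                        )
                    )
                    i += 1
            sents.append(Sentence(tuple(toks)))
        docs.append(Document(doc_id=f"r{di}", sentences=tuple(sents)))
    return LabeledCorpus(tuple(docs))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
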