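"""Core in-memory containers for BIO-labeled corpora.

A corpus is a list of documents; a document an ordered list of sentences;
a sentence an ordered list of tokens.  Each token carries a surface form,
a BIO tag (``O`` or ``B-Type``/``I-Type``) and an optional per-token
confidence in ``[0, 1]`` as emitted by an upstream tagger.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional


class BioError(ValueError):
    """A label violates the BIO scheme."""


@dataclass(frozen=True)
class Token:
    text: str
    label: str = "O"
    confidence: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("token text must be non-empty")
        if self.label != "O" and not (
            self.label.startswith("B-") or self.label.startswith("I-")
        ):
            raise BioError(f"label {self.label!r} is not 'O', 'B-*' or 'I-*'")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def core_type(self) -> Optional[str]:
        """Entity type without the BIO prefix; None for 'O'."""
        return None if self.label == "O" else self.label[2:]


@dataclass(frozen=True)
class Sentence:
    tokens: tuple[Token, ...]

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("sentence must contain at least one token")

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[Token]:
        return iter(self.tokens)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(t.label for t in self.tokens)

    @property
    def texts(self) -> tuple[str, ...]:
        return tuple(t.text for t in self.tokens)


@dataclass(frozen=True)
class Document:
    doc_id: str
    sentences: tuple[Sentence, ...] = ()
    provenance: str = "original"  # original | augmented
    set_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.provenance not in ("original", "augmented"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.provenance == "original" and self.set_ids:
            raise ValueError("original document must not carry synthetic set ids")

    def __len__(self) -> int:
        return sum(len(s) for s in self.sentences)

    def iter_tokens(self) -> Iterator[Token]:
        for s in self.sentences:
            yield from s.tokens


@dataclass(frozen=True)
class LabeledCorpus:
    documents: tuple[Document, ...] = ()

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for d in self.documents:
            if d.doc_id in seen:
                raise ValueError(f"duplicate doc_id {d.doc_id!r}")
            seen.add(d.doc_id)

    def __len__(self) -> int:
        return len(self.documents)

    @property
    def n_tokens(self) -> int:
        return sum(len(d) for d in self.documents)

    @property
    def n_sentences(self) -> int:
        return sum(len(d.sentences) for d in self.documents)

    def iter_tokens(self) -> Iterator[Token]:
        for d in self.documents:
            yield from d.iter_tokens()

    def labels_used(self) -> set[str]:
        return {t.label for t in self.iter_tokens()}

    def map_tokens(self, fn) -> "LabeledCorpus":
        """Structure-preserving per-token rewrite: fn(Token) -> Token."""
        docs = []
        for d in self.documents:
            sents = tuple(
                Sentence(tuple(fn(t) for t in s.tokens)) for s in d.sentences
            )
            docs.append(replace(d, sentences=sents))
        return LabeledCorpus(tuple(docs))


def bio_violations(labels: tuple[str, ...]) -> list[int]:
    """Indices of dangling I- tokens (no matching B-/I- of the same type before)."""
    bad = []
    prev_type: Optional[str] = None
    for i, lab in enumerate(labels):
        if lab.startswith("I-"):
            if prev_type != lab[2:]:
                bad.append(i)
            # a dangling I- still opens a run of its type
            prev_type = lab[2:]
        elif lab.startswith("B-"):
            prev_type = lab[2:]
        else:
            prev_type = None
    return bad


def repair_bio(corpus: LabeledCorpus, warn: bool = True) -> LabeledCorpus:
    """Rewrite dangling ``I-X`` tokens to ``B-X``.

    Noisy upstream taggers occasionally emit an inside tag with no opener;
    the repair is explicit rather than silent so counts can be audited.
    """
    n_repaired = 0
    docs = []
    for d in corpus.documents:
        sents = []
        for s in d.sentences:
            bad = set(bio_violations(s.labels))
            if bad:
                n_repaired += len(bad)
                toks = tuple(
                    replace(t, label="B-" + t.label[2:]) if i in bad else t
                    for i, t in enumerate(s.tokens)
                )
                sents.append(Sentence(toks))
            else:
                sents.append(s)
        docs.append(replace(d, sentences=tuple(sents)))
    if n_repaired and warn:
        warnings.warn(f"repaired {n_repaired} dangling I- label(s) to B-")
    return LabeledCorpus(tuple(docs))


def validate_bio(corpus: LabeledCorpus) -> None:
    """Raise BioError on the first dangling I- token."""
    for d in corpus.documents:
        for si, s in enumerate(d.sentences):
            bad = bio_violations(s.labels)
            if bad:
                raise BioError(
                    f"dangling I- label in document {d.doc_id!r}, "
                    f"sentence {si}, token {bad[0]}"
                )
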