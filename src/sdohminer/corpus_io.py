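"""CoNLL 2003-style reading/writing and sentence-preserving segmentation.

Dialect: whitespace-delimited columns, token first, BIO label next, an
optional trailing confidence column in ``[0, 1]``; blank lines separate
sentences; a configurable marker line (default ``-DOCSTART-``) separates
documents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from .corpus import Document, LabeledCorpus, Sentence, Token


class ConllParseError(ValueError):
    pass


@dataclass(frozen=True)
class ConllDialect:
    doc_marker: str = "-DOCSTART-"
    sep: Optional[str] = None  # None = any whitespace
    write_confidence: bool = True


def _parse_line(line: str, lineno: int, dialect: ConllDialect) -> Token:
    fields = line.split(dialect.sep)
    if len(fields) not in (2, 3):
        raise ConllParseError(
            f"line {lineno}: expected 2 or 3 fields, got {len(fields)}: {line!r}"
        )
    text, label = fields[0], fields[1]
    conf: Optional[float] = None
    if len(fields) == 3:
        try:
            conf = float(fields[2])
        except ValueError as exc:
            raise ConllParseError(
                f"line {lineno}: confidence {fields[2]!r} is not a number"
            ) from exc
        if not (0.0 <= conf <= 1.0):
            raise ConllParseError(
                f"line {lineno}: confidence {conf} outside [0, 1]"
            )
    return Token(text=text, label=label, confidence=conf)


def read_conll(
    path: Union[str, Path],
    dialect: ConllDialect = ConllDialect(),
    schema=None,
) -> LabeledCorpus:
    """Parse a CoNLL file into a :class:`LabeledCorpus`.

    Blank line = sentence boundary; a line starting with the document
    marker opens a new document.  When ``schema`` (a LabelSchema) is given,
    labels outside its BIO expansion raise a validation error.
    """
    path = Path(path)
    docs: list[Document] = []
    cur_sents: list[Sentence] = []
    cur_toks: list[Token] = []
    doc_open = False
    n_anon = 0

    def flush_sentence() -> None:
        nonlocal cur_toks
        if cur_toks:
            cur_sents.append(Sentence(tuple(cur_toks)))
            cur_toks = []

    def flush_document() -> None:
        nonlocal cur_sents, doc_open, n_anon
        flush_sentence()
        if doc_open or cur_sents:
            docs.append(
                Document(doc_id=f"doc-{len(docs):05d}", sentences=tuple(cur_sents))
            )
            cur_sents = []
        doc_open = False

    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                flush_sentence()
                continue
            if line.split(dialect.sep)[0] == dialect.doc_marker:
                flush_document()
                doc_open = True
                continue
            cur_toks.append(_parse_line(line, lineno, dialect))
    flush_document()

    corpus = LabeledCorpus(tuple(docs))
    if schema is not None:
        allowed = set(schema.expanded_labels)
        unknown = sorted(corpus.labels_used() - allowed)
        if unknown:
            raise ConllParseError(f"labels outside schema: {unknown}")
    return corpus


def write_conll(
    corpus: LabeledCorpus,
    path: Union[str, Path],
    dialect: ConllDialect = ConllDialect(),
) -> None:
    """Serialize so that ``read_conll(write_conll(c)) == c`` field-wise."""
    sep = dialect.sep or " "
    with Path(path).open("w", encoding="utf-8") as fh:
        for d in corpus.documents:
            fh.write(dialect.doc_marker + "\n\n")
            for s in d.sentences:
                for t in s.tokens:
                    if t.confidence is not None and dialect.write_confidence:
                        fh.write(f"{t.text}{sep}{t.label}{sep}{t.confidence:.6g}\n")
                    else:
                        fh.write(f"{t.text}{sep}{t.label}\n")
                fh.write("\n")


class SentenceTooLongError(ValueError):
    pass


def segment_document(
    doc: Document, max_tokens: int = 512, hard_split: bool = False
) -> list[tuple[Token, ...]]:
    """Greedy packing of whole sentences into segments of <= ``max_tokens``.

    Sentences are never split across segments, so local context survives the
    fixed-window encoders downstream.  A single sentence longer than the
    window raises by default; with ``hard_split`` it is cut at window
    boundaries and a warning logged.
    """
    if max_tokens < 1:
        raise ValueError("max_tokens must be positive")
    segments: list[tuple[Token, ...]] = []
    cur: list[Token] = []
    for si, s in enumerate(doc.sentences):
        if len(s) > max_tokens:
            if not hard_split:
                raise SentenceTooLongError(
                    f"sentence {si} of document {doc.doc_id!r} has {len(s)} tokens "
                    f"(> {max_tokens}); pass hard_split=True to cut it"
                )
            warnings.warn(
                f"hard-splitting {len(s)}-token sentence {si} "
                f"in document {doc.doc_id!r}"
            )
            if cur:
                segments.append(tuple(cur))
                cur = []
            toks = list(s.tokens)
            while toks:
                segments.append(tuple(toks[:max_tokens]))
                toks = toks[max_tokens:]
            continue
        if len(cur) + len(s) > max_tokens:
            segments.append(tuple(cur))
            cur = []
        cur.extend(s.tokens)
    if cur:
        segments.append(tuple(cur))
    return segments


_PUNCT = set(".,;:!?()[]{}\"'`%/\\")


def tokenize_text(text: str) -> list[str]:
    """Deterministic whitespace + punctuation word tokenizer for raw text."""
    out: list[str] = []
    for chunk in text.split():
        buf = ""
        for ch in chunk:
            if ch in _PUNCT:
                if buf:
                    out.append(buf)
                    buf = ""
                out.append(ch)
            else:
                buf += ch
        if buf:
            out.append(buf)
    return out
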