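"""Corpus cleaning rules applied between automatic tagging and training.

Three rules, in pipeline order: (1) demote low-confidence entity labels to
'O' (floor 0.90, strict ``<``); (2) demote numeric tokens labeled as
anything but Age; (3) drop sentences containing only 'O' labels — the last
for training subsets only, since it changes the class prior.
All three are idempotent and structure-preserving apart from the dropped
sentences.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace

from .corpus import Document, LabeledCorpus, Sentence, Token

#: digits, optionally with thousands separators, one decimal point, leading sign
NUMERIC_PATTERN = re.compile(r"^[+-]?\d{1,3}(,\d{3})*(\.\d+)?$|^[+-]?\d+(\.\d+)?$")


@dataclass(frozen=True)
class FiltrationConfig:
    confidence_floor: float = 0.90
    drop_all_O: bool = True  # training subsets only
    prune_empty_documents: bool = False
    numeric_pattern: re.Pattern = NUMERIC_PATTERN

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence_floor <= 1.0):
            raise ValueError(
                f"confidence_floor {self.confidence_floor} outside [0, 1]"
            )


def is_numeric_token(text: str, pattern: re.Pattern = NUMERIC_PATTERN) -> bool:
    return bool(pattern.match(text))


def apply_confidence_floor(corpus: LabeledCorpus, floor: float = 0.90) -> LabeledCorpus:
    """Relabel entity tokens with confidence strictly below ``floor`` as 'O'.

    Tokens without a confidence are exempt (human-reviewed labels carry none).
    """
    if not (0.0 <= floor <= 1.0):
        raise ValueError(f"floor {floor} outside [0, 1]")

    def demote(t: Token) -> Token:
        if t.label != "O" and t.confidence is not None and t.confidence < floor:
            return replace(t, label="O")
        return t

    return corpus.map_tokens(demote)


def demote_numeric_nonage(
    corpus: LabeledCorpus, pattern: re.Pattern = NUMERIC_PATTERN
) -> LabeledCorpus:
    """Relabel numeric tokens as 'O' unless tagged B-Age/I-Age.

    Misclassified dates, doses and lab values are the dominant numeric noise
    source; ages are the one numeric entity kept.
    """

    def demote(t: Token) -> Token:
        if (
            t.label not in ("O", "B-Age", "I-Age")
            and is_numeric_token(t.text, pattern)
        ):
            return replace(t, label="O")
        return t

    return corpus.map_tokens(demote)


def drop_all_O_sentences(
    corpus: LabeledCorpus, prune_empty_documents: bool = False
) -> LabeledCorpus:
    """Remove sentences whose labels are all 'O'; keep document order.

    Documents emptied entirely are retained as empty shells (with a warning)
    so corpus accounting stays stable; ``prune_empty_documents`` removes them.
    """
    docs: list[Document] = []
    n_emptied = 0
    for d in corpus.documents:
        kept = tuple(
            s for s in d.sentences if any(t.label != "O" for t in s.tokens)
        )
        if not kept and d.sentences:
            n_emptied += 1
            if prune_empty_documents:
                continue
        docs.append(replace(d, sentences=kept))
    if n_emptied and not prune_empty_documents:
        warnings.warn(
            f"{n_emptied} document(s) left empty after all-'O' sentence removal"
        )
    return LabeledCorpus(tuple(docs))


def apply_filtration(
    corpus: LabeledCorpus,
    cfg: FiltrationConfig = FiltrationConfig(),
    refinement=None,
) -> LabeledCorpus:
    """Full cleaning pass in the fixed order:

    confidence floor -> label refinement (optional) -> numeric demotion ->
    all-'O' sentence removal (training regime only).
    """
    out = apply_confidence_floor(corpus, cfg.confidence_floor)
    if refinement is not None:
        from .label_schema import refine_labels

        out = refine_labels(out, refinement)
    out = demote_numeric_nonage(out, cfg.numeric_pattern)
    if cfg.drop_all_O:
        out = drop_all_O_sentences(out, cfg.prune_empty_documents)
    return out
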