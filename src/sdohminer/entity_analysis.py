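"""Mention-level corpus analyses: entity richness, frequency shares, and
ordered entity-type trigrams.

A mention is a maximal ``B-X (I-X)*`` token run of one type; all analyses
here count mentions, not tokens.  Trigrams slide a width-3 window (stride
1) over each document's mention-type sequence — across sentence boundaries
by default, since the document is the analysis unit — optionally
restricted to the most frequent types.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .corpus import BioError, Document, LabeledCorpus


@dataclass(frozen=True)
class EntityMention:
    doc_id: str
    entity_type: str
    surface: str
    start: int  # token index within the document
    length: int


def collapse_mentions(doc: Document, strict: bool = True) -> list[EntityMention]:
    """Collapse BIO runs into mentions, in document order.

    With ``strict`` (default) a dangling ``I-`` raises; run the corpus
    through ``repair_bio`` first if the upstream tagger is noisy.
    """
    mentions: list[EntityMention] = []
    cur_type: str | None = None
    cur_words: list[str] = []
    cur_start = 0
    pos = 0

    def close() -> None:
        nonlocal cur_type, cur_words
        if cur_type is not None:
            mentions.append(
                EntityMention(
                    doc_id=doc.doc_id,
                    entity_type=cur_type,
                    surface=" ".join(cur_words),
                    start=cur_start,
                    length=len(cur_words),
                )
            )
        cur_type, cur_words = None, []

    for sent in doc.sentences:
        for tok in sent.tokens:
            lab = tok.label
            if lab.startswith("B-"):
                close()
                cur_type, cur_words, cur_start = lab[2:], [tok.text], pos
            elif lab.startswith("I-"):
                if cur_type != lab[2:]:
                    if strict:
                        raise BioError(
                            f"dangling {lab!r} at token {pos} of document "
                            f"{doc.doc_id!r}; repair the corpus first"
                        )
                    close()
                    cur_type, cur_words, cur_start = lab[2:], [tok.text], pos
                else:
                    cur_words.append(tok.text)
            else:
                close()
            pos += 1
        close()  # mentions do not span sentence boundaries
    return mentions


def all_mentions(corpus: LabeledCorpus, strict: bool = True) -> list[EntityMention]:
    out: list[EntityMention] = []
    for d in corpus.documents:
        out.extend(collapse_mentions(d, strict=strict))
    return out


def entity_richness(corpus: LabeledCorpus) -> tuple[pd.Series, pd.Series]:
    """Distinct non-'O' mention types per document, plus the histogram.

    Returns ``(per_document, histogram)``: per-document counts indexed by
    doc_id, and a histogram over richness values indexed ascending.
    """
    per_doc = {}
    for d in corpus.documents:
        per_doc[d.doc_id] = len({m.entity_type for m in collapse_mentions(d)})
    s = pd.Series(per_doc, name="richness", dtype=int)
    hist = s.value_counts().sort_index()
    hist.name = "n_documents"
    return s, hist


def frequency_table(corpus: LabeledCorpus) -> pd.Series:
    """Percent of all non-'O' mentions per entity type, sorted descending."""
    counts = Counter(m.entity_type for m in all_mentions(corpus))
    if not counts:
        raise ValueError("corpus contains no entity mentions")
    total = sum(counts.values())
    s = pd.Series(
        {k: 100.0 * v / total for k, v in counts.items()}, name="percent"
    )
    return s.sort_values(ascending=False, kind="stable")


def trigram_frequencies(
    corpus: LabeledCorpus,
    top_k: int = 25,
    break_at_dropped: bool = False,
    within_sentence: bool = False,
) -> pd.Series:
    """Ordered entity-type trigram shares over document mention sequences.

    Only mentions of the ``top_k`` most frequent types participate.  By
    default dropped mentions are removed from the sequence before windowing
    (windows may span a dropped mention); ``break_at_dropped`` instead
    breaks sequences there.  Shares are percent of all counted trigrams and
    sum to 100 over the full table.
    """
    freq = frequency_table(corpus)
    top = set(freq.index[:top_k])
    counts: Counter[tuple[str, str, str]] = Counter()

    def windows(seq: list[str]) -> None:
        for i in range(len(seq) - 2):
            counts[tuple(seq[i : i + 3])] += 1

    for d in corpus.documents:
        if within_sentence:
            groups = []
            pos = 0
            mentions = collapse_mentions(d)
            for s in d.sentences:
                end = pos + len(s)
                groups.append(
                    [m.entity_type for m in mentions if pos <= m.start < end]
                )
                pos = end
        else:
            groups = [[m.entity_type for m in collapse_mentions(d)]]
        for g in groups:
            if break_at_dropped:
                run: list[str] = []
                for t in g + ["\x00"]:
                    if t in top:
                        run.append(t)
                    else:
                        windows(run)
                        run = []
            else:
                windows([t for t in g if t in top])

    if not counts:
        raise ValueError("no document contributes an eligible trigram")
    total = sum(counts.values())
    s = pd.Series(
        {k: 100.0 * v / total for k, v in counts.items()}, name="percent"
    )
    return s.sort_values(ascending=False, kind="stable")
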