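"""Segment encoding for fixed-window and padded-sequence taggers.

Transformer-style encoding wraps each <=512-token segment in start/separator
markers, expands words into deterministic subword pieces, pads to the fixed
window and aligns labels so that only the first piece of each word carries
the word's label; continuation pieces and special positions are ignored in
the loss.  Recurrent taggers get plain padded word-id sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from ..corpus import LabeledCorpus, Token

PAD, UNK, CLS, SEP = "[PAD]", "[UNK]", "[CLS]", "[SEP]"
IGNORE_INDEX = -100
_PIECE_LEN = 4
_MAX_WORD_LEN = 8  # words longer than this are split into pieces


def subword_pieces(word: str) -> list[str]:
    """Deterministic wordpiece-style split: short words stay whole, longer
    words become fixed-width chunks with '##' continuation markers."""
    if len(word) <= _MAX_WORD_LEN:
        return [word]
    pieces = [word[:_PIECE_LEN]]
    for i in range(_PIECE_LEN, len(word), _PIECE_LEN):
        pieces.append("##" + word[i : i + _PIECE_LEN])
    return pieces


class Vocab:
    """Bidirectional piece/word <-> id map with reserved specials."""

    def __init__(self, tokens: Iterable[str]):
        self._itos: list[str] = [PAD, UNK, CLS, SEP]
        seen = set(self._itos)
        for t in tokens:
            if t not in seen:
                self._itos.append(t)
                seen.add(t)
        self._stoi = {t: i for i, t in enumerate(self._itos)}

    def __len__(self) -> int:
        return len(self._itos)

    def id(self, token: str) -> int:
        return self._stoi.get(token, self._stoi[UNK])

    def token(self, idx: int) -> str:
        return self._itos[idx]

    @classmethod
    def from_corpus(cls, corpus: LabeledCorpus, subword: bool = False) -> "Vocab":
        toks: list[str] = []
        for t in corpus.iter_tokens():
            toks.extend(subword_pieces(t.text) if subword else [t.text])
        return cls(toks)

    @classmethod
    def from_segments(
        cls, segments: Sequence[Sequence[Token]], subword: bool = False
    ) -> "Vocab":
        toks: list[str] = []
        for seg in segments:
            for t in seg:
                toks.extend(subword_pieces(t.text) if subword else [t.text])
        return cls(toks)


@dataclass
class EncodedBatch:
    input_ids: np.ndarray  # (max_len,) int
    attention_mask: np.ndarray  # (max_len,) int, 1 on non-pad positions
    label_ids: np.ndarray  # (max_len,) int, IGNORE_INDEX off first-pieces
    n_truncated_words: int = 0


def encode(
    segments: Sequence[Sequence[Token]],
    vocab: Vocab,
    label_list: Sequence[str],
    max_len: int = 512,
) -> list[EncodedBatch]:
    """Transformer-style encoding of token segments.

    Words overflowing the window after subword expansion are truncated with
    a warning; the per-batch truncation count is reported on the batch.
    """
    label_to_id = {lab: i for i, lab in enumerate(label_list)}
    out: list[EncodedBatch] = []
    total_truncated = 0
    for seg in segments:
        ids = [vocab.id(CLS)]
        labs = [IGNORE_INDEX]
        n_trunc = 0
        if not seg:  # degenerate: an empty segment encodes to all-pad
            out.append(
                EncodedBatch(
                    input_ids=np.zeros(max_len, dtype=np.int64),
                    attention_mask=np.zeros(max_len, dtype=np.int64),
                    label_ids=np.full(max_len, IGNORE_INDEX, dtype=np.int64),
                )
            )
            continue
        for tok in seg:
            pieces = subword_pieces(tok.text)
            if len(ids) + len(pieces) + 1 > max_len:  # +1 for SEP
                n_trunc += 1
                continue
            for k, p in enumerate(pieces):
                ids.append(vocab.id(p))
                labs.append(
                    label_to_id[tok.label] if k == 0 else IGNORE_INDEX
                )
        ids.append(vocab.id(SEP))
        labs.append(IGNORE_INDEX)
        mask = [1] * len(ids)
        pad_n = max_len - len(ids)
        input_ids = np.asarray(ids + [vocab.id(PAD)] * pad_n, dtype=np.int64)
        attention = np.asarray(mask + [0] * pad_n, dtype=np.int64)
        label_ids = np.asarray(labs + [IGNORE_INDEX] * pad_n, dtype=np.int64)
        total_truncated += n_trunc
        out.append(
            EncodedBatch(
                input_ids=input_ids,
                attention_mask=attention,
                label_ids=label_ids,
                n_truncated_words=n_trunc,
            )
        )
    if total_truncated:
        warnings.warn(
            f"{total_truncated} word(s) truncated during subword encoding"
        )
    return out


def decode(
    batches: Sequence[EncodedBatch],
    vocab: Vocab,
    label_list: Sequence[str],
) -> list[list[tuple[str, str]]]:
    """Invert :func:`encode` on masked positions: per segment, the (text,
    label) sequence of non-truncated words (exact when the vocab covers all
    pieces)."""
    out = []
    for b in batches:
        words: list[tuple[str, str]] = []
        cur_word: Optional[str] = None
        cur_label: Optional[str] = None
        for idx, m, lab in zip(b.input_ids, b.attention_mask, b.label_ids):
            if not m:
                break
            piece = vocab.token(int(idx))
            if piece in (CLS, SEP, PAD):
                continue
            if piece.startswith("##") and cur_word is not None:
                cur_word += piece[2:]
                continue
            if cur_word is not None:
                words.append((cur_word, cur_label))
            cur_word = piece
            cur_label = label_list[int(lab)] if lab != IGNORE_INDEX else "O"
        if cur_word is not None:
            words.append((cur_word, cur_label))
        out.append(words)
    return out


def encode_padded(
    segments: Sequence[Sequence[Token]],
    vocab: Vocab,
    label_list: Sequence[str],
    max_len: int = 512,
) -> list[EncodedBatch]:
    """Plain padded word-id sequences (no specials, no subwords) for the
    recurrent model families."""
    label_to_id = {lab: i for i, lab in enumerate(label_list)}
    out = []
    for seg in segments:
        if len(seg) > max_len:
            raise ValueError(f"segment of {len(seg)} tokens exceeds {max_len}")
        ids = [vocab.id(t.text) for t in seg]
        labs = [label_to_id[t.label] for t in seg]
        pad_n = max_len - len(ids)
        out.append(
            EncodedBatch(
                input_ids=np.asarray(ids + [vocab.id(PAD)] * pad_n, dtype=np.int64),
                attention_mask=np.asarray(
                    [1] * len(seg) + [0] * pad_n, dtype=np.int64
                ),
                label_ids=np.asarray(
                    labs + [IGNORE_INDEX] * pad_n, dtype=np.int64
                ),
            )
        )
    return out
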