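"""Training orchestration for the tagger families.

Defaults are desk-scale; the published full-scale regimes (long
fine-tuning at 1e-5 for transformer encoders, 10 epochs at 1e-9 for the
recurrent baselines) ship as named presets rather than defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from ..corpus import LabeledCorpus
from .encoding import Vocab
from .models import MODEL_FAMILIES, RecurrentTagger


@dataclass(frozen=True)
class TrainConfig:
    model_family: str = "gru"
    epochs: int = 15
    learning_rate: float = 1e-2
    embed_dim: int = 24
    hidden_size: int = 32
    dropout: float = 0.1
    class_weighting: str = "inverse"  # inverse | none
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs <= 0:
            raise ValueError("epochs must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.class_weighting not in ("inverse", "none"):
            raise ValueError(f"unknown class_weighting {self.class_weighting!r}")


#: Published full-scale regimes, selectable by name.
PRESETS: dict[str, TrainConfig] = {
    "paper_transformer": TrainConfig(
        model_family="transformer_finetune", epochs=300, learning_rate=1e-5
    ),
    "paper_recurrent": TrainConfig(
        model_family="bilstm", epochs=10, learning_rate=1e-9
    ),
}


def inverse_frequency_weights(
    corpus: LabeledCorpus, label_list: Sequence[str]
) -> np.ndarray:
    """Per-label weights 1/frequency, normalized to mean 1 over the labels
    present; absent labels get weight 1."""
    counts = np.zeros(len(label_list))
    idx = {lab: i for i, lab in enumerate(label_list)}
    for t in corpus.iter_tokens():
        counts[idx[t.label]] += 1
    w = np.ones(len(label_list))
    present = counts > 0
    w[present] = 1.0 / counts[present]
    w[present] /= w[present].mean()
    return w


def split_documents(
    corpus: LabeledCorpus, train_fraction: float = 0.8, seed: int = 0
) -> tuple[LabeledCorpus, LabeledCorpus]:
    """Document-level random split (unstratified, seeded)."""
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus.documents))
    n_train = int(round(train_fraction * len(order)))
    train_idx = set(order[:n_train].tolist())
    tr = tuple(d for i, d in enumerate(corpus.documents) if i in train_idx)
    te = tuple(d for i, d in enumerate(corpus.documents) if i not in train_idx)
    return LabeledCorpus(tr), LabeledCorpus(te)


def _sequences(
    corpus: LabeledCorpus, vocab: Vocab, label_list: Sequence[str]
) -> list[tuple[np.ndarray, np.ndarray]]:
    lab_idx = {lab: i for i, lab in enumerate(label_list)}
    seqs = []
    for d in corpus.documents:
        for s in d.sentences:
            ids = np.asarray([vocab.id(t.text) for t in s.tokens], dtype=np.int64)
            labs = np.asarray([lab_idx[t.label] for t in s.tokens], dtype=np.int64)
            seqs.append((ids, labs))
    return seqs


def train(
    corpus: LabeledCorpus,
    label_list: Sequence[str],
    cfg: TrainConfig = TrainConfig(),
    vocab: Optional[Vocab] = None,
    sample_weights: Optional[Sequence[np.ndarray]] = None,
):
    """Fit a tagger of ``cfg.model_family`` on the corpus.

    Labels outside ``label_list`` raise before training.  Returns a fitted
    tagger exposing ``predict_scores``/``predict_labels`` and
    ``loss_history``.
    """
    unknown = set(corpus.labels_used()) - set(label_list)
    if unknown:
        raise ValueError(f"corpus labels outside schema: {sorted(unknown)}")
    factory = MODEL_FAMILIES.get(cfg.model_family)
    if factory is None:
        raise ValueError(f"unknown model family {cfg.model_family!r}")
    if cfg.model_family == "transformer_finetune":
        factory()  # raises BackendUnavailableError unless one was registered
    if vocab is None:
        vocab = Vocab.from_corpus(corpus)
    tagger: RecurrentTagger = factory(
        vocab=vocab,
        label_list=list(label_list),
        embed_dim=cfg.embed_dim,
        hidden_size=cfg.hidden_size,
        dropout=cfg.dropout,
        seed=cfg.seed,
    )
    cw = (
        inverse_frequency_weights(corpus, label_list)
        if cfg.class_weighting == "inverse"
        else None
    )
    tagger.fit(
        _sequences(corpus, vocab, label_list),
        epochs=cfg.epochs,
        learning_rate=cfg.learning_rate,
        class_weights=cw,
        sample_weights=sample_weights,
        batch_size=cfg.batch_size,
        shuffle_seed=cfg.seed,
    )
    return tagger
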