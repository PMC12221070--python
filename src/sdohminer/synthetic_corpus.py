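"""Seeded generator of case-report-like labeled corpora.

Emulates the statistical structure of automatically tagged clinical
case-report text — heavy 'O' dominance, strongly skewed entity-type
frequencies (condition mentions dominant, race/sexual-orientation well
under 1%), multi-token entity spans, per-token tagger confidences, and a
controllable rate of label noise — so every downstream stage is testable
without the real corpus.  No attempt is made at linguistic realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .corpus import Document, LabeledCorpus, Sentence, Token
from .label_schema import DEFAULT_CORE_TYPES

#: Per-type surface vocabulary.  Ages are digit strings so the numeric
#: demotion rule downstream is exercised; every type keeps at least one
#: single-word variant so spans always fit; several multi-word variants
#: exercise B-/I- span handling.
SURFACE_VOCAB: dict[str, tuple[str, ...]] = {
    "Access_To_Care": ("clinic", "admission", "telehealth consult", "delayed care"),
    "Age": (),  # drawn as digits at generation time
    "Condition": ("myocarditis", "dysautonomia", "chronic fatigue", "pulmonary fibrosis", "anosmia"),
    "Diet": ("vegan", "low sodium diet", "fasting"),
    "Disability": ("deafness", "mobility limitation", "paraplegia"),
    "Education": ("undergraduate", "high school diploma", "illiterate"),
    "Employment": ("nurse", "factory worker", "unemployed"),
    "Exercise": ("jogging", "daily walking", "sedentary"),
    "Family_Member": ("sibling", "her daughter", "his grandfather"),
    "Gender": ("female", "male", "non binary"),
    "Geographic_Entity": ("Nairobi", "rural Guatemala", "northern Ontario"),
    "Housing": ("shelter", "homeless shelter", "overcrowded apartment"),
    "Income": ("poverty", "low income", "fixed pension"),
    "Insurance_Status": ("uninsured", "medicaid coverage", "private insurance"),
    "Language": ("tagalog", "haitian creole", "amharic"),
    "Marital_Status": ("widowed", "never married", "divorced"),
    "Mental_Health": ("ptsd", "severe anxiety", "postpartum depression"),
    "Race_Ethnicity": ("indigenous", "afro caribbean", "south asian"),
    "Severity": ("critical", "life threatening", "mild"),
    "Sexual_Orientation": ("bisexual", "gay", "asexual"),
    "Social_Support": ("isolated", "peer support group", "church volunteers"),
    "Spiritual_Beliefs": ("buddhist", "evangelical faith", "animist beliefs"),
    "Substance": ("vaping", "heavy drinking", "intravenous drug use"),
    "Treatment": ("dialysis", "plasma exchange", "corticosteroid taper"),
    "Vaccine": ("booster", "two dose series", "unvaccinated status"),
    "Violence_Or_Abuse": ("assault", "domestic violence", "childhood abuse"),
}

#: Non-entity filler vocabulary for 'O' tokens.
O_VOCAB: tuple[str, ...] = (
    "the", "patient", "was", "presented", "with", "history", "of", "and",
    "reported", "on", "examination", "showed", "symptoms", "after",
    "infection", "during", "admission", "noted", "had", "a",
)


def default_type_frequencies() -> dict[str, float]:
    """Skewed per-type shares of non-'O' tokens, condition-heavy with
    sensitive categories well below 1%, mirroring real case-report text."""
    named = {
        "Condition": 0.3727,
        "Age": 0.1011,
        "Access_To_Care": 0.0774,
        "Treatment": 0.0756,
        "Severity": 0.0536,
        "Mental_Health": 0.0515,
        "Gender": 0.0466,
        "Substance": 0.0433,
        "Housing": 0.0030,
        "Spiritual_Beliefs": 0.0027,
        "Sexual_Orientation": 0.0018,
        "Race_Ethnicity": 0.0005,
    }
    rest = [t for t in DEFAULT_CORE_TYPES if t not in named]
    remainder = (1.0 - sum(named.values())) / len(rest)
    out = dict(named)
    out.update({t: remainder for t in rest})
    return out


@dataclass(frozen=True)
class ConfidenceModel:
    """Tagger-confidence distributions for correct vs. corrupted labels."""

    true_beta: tuple[float, float] = (1.0, 12.0)  # conf = 1 - Beta(a, b)
    spurious_range: tuple[float, float] = (0.2, 0.9)
    o_has_confidence: bool = True


@dataclass(frozen=True)
class CorpusSpec:
    n_documents: int = 20
    sentences_per_doc: tuple[int, int] = (5, 15)
    tokens_per_sentence: tuple[int, int] = (6, 25)
    type_frequencies: Mapping[str, float] = field(
        default_factory=default_type_frequencies
    )
    o_share: float = 0.85
    noise_rate: float = 0.0
    confidence_model: Optional[ConfidenceModel] = ConfidenceModel()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.o_share <= 1.0):
            raise ValueError("o_share outside [0, 1]")
        if not (0.0 <= self.noise_rate < 1.0):
            raise ValueError("noise_rate outside [0, 1)")
        total = sum(self.type_frequencies.values())
        if self.type_frequencies and abs(total - 1.0) > 1e-6:
            raise ValueError(f"type_frequencies sum to {total}, expected 1")
        for t in self.type_frequencies:
            if t != "Age" and t not in SURFACE_VOCAB:
                raise ValueError(f"no surface vocabulary for type {t!r}")
        lo, hi = self.tokens_per_sentence
        max_span = max(
            (len(v.split()) for vs in SURFACE_VOCAB.values() for v in vs),
            default=1,
        )
        if lo < 1 or hi < lo:
            raise ValueError("bad tokens_per_sentence range")
        if hi < max_span:
            raise ValueError(
                f"sentences of at most {hi} tokens cannot hold "
                f"{max_span}-token entity spans"
            )


def generate_entity_surface(
    entity_type: str, rng: np.random.Generator, max_words: Optional[int] = None
) -> str:
    """Draw a surface form for one entity mention."""
    if entity_type == "Age":
        return str(int(rng.integers(1, 100)))
    if entity_type not in SURFACE_VOCAB:
        raise KeyError(f"unknown entity type {entity_type!r}")
    pool = SURFACE_VOCAB[entity_type]
    if max_words is not None:
        pool = tuple(v for v in pool if len(v.split()) <= max_words)
        if not pool:
            raise ValueError(
                f"no {entity_type} variant fits in {max_words} token(s)"
            )
    return pool[int(rng.integers(len(pool)))]


def _mention_weights(freqs: Mapping[str, float]) -> tuple[list[str], np.ndarray]:
    """Type-selection weights p_t / E[len_t], so that *token* shares converge
    to the requested type_frequencies despite multi-token spans."""
    types, w = [], []
    for t, p in freqs.items():
        if p <= 0:
            continue
        if t == "Age":
            mean_len = 1.0
        else:
            mean_len = float(
                np.mean([len(v.split()) for v in SURFACE_VOCAB[t]])
            )
        types.append(t)
        w.append(p / mean_len)
    weights = np.asarray(w, dtype=float)
    return types, weights / weights.sum()


def generate_corpus(spec: CorpusSpec) -> tuple[LabeledCorpus, LabeledCorpus]:
    """Generate ``(observed, truth)`` corpora under ``spec``.

    ``truth`` holds the pre-noise labels (no confidences); ``observed``
    carries the corrupted labels and tagger-style confidences.  Both share
    identical text and structure and are deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    types, weights = (
        _mention_weights(spec.type_frequencies)
        if spec.type_frequencies
        else ([], np.array([]))
    )
    cm = spec.confidence_model
    all_labels = [f"B-{t}" for t in DEFAULT_CORE_TYPES]

    obs_docs, true_docs = [], []
    for di in range(spec.n_documents):
        n_sent = int(rng.integers(spec.sentences_per_doc[0], spec.sentences_per_doc[1] + 1))
        obs_sents, true_sents = [], []
        for _ in range(n_sent):
            n_tok = int(
                rng.integers(spec.tokens_per_sentence[0], spec.tokens_per_sentence[1] + 1)
            )
            texts: list[str] = []
            labels: list[str] = []
            while len(texts) < n_tok:
                remaining = n_tok - len(texts)
                if not types or rng.random() < spec.o_share:
                    texts.append(O_VOCAB[int(rng.integers(len(O_VOCAB)))])
                    labels.append("O")
                    continue
                t = types[int(rng.choice(len(types), p=weights))]
                try:
                    surface = generate_entity_surface(t, rng, max_words=remaining)
                except ValueError:
                    texts.append(O_VOCAB[int(rng.integers(len(O_VOCAB)))])
                    labels.append("O")
                    continue
                words = surface.split()
                texts.extend(words)
                labels.append(f"B-{t}")
                labels.extend(f"I-{t}" for _ in words[1:])

            obs_toks, true_toks = [], []
            for text, lab in zip(texts, labels):
                noisy_lab = lab
                corrupted = False
                if spec.noise_rate and rng.random() < spec.noise_rate:
                    corrupted = True
                    if lab == "O":
                        noisy_lab = all_labels[int(rng.integers(len(all_labels)))]
                    else:
                        noisy_lab = "O"
                conf = None
                if cm is not None:
                    if corrupted:
                        conf = float(rng.uniform(*cm.spurious_range))
                    elif noisy_lab != "O" or cm.o_has_confidence:
                        a, b = cm.true_beta
                        conf = float(1.0 - rng.beta(a, b))
                true_toks.append(Token(text=text, label=lab))
                obs_toks.append(Token(text=text, label=noisy_lab, confidence=conf))
            obs_sents.append(Sentence(tuple(obs_toks)))
            true_sents.append(Sentence(tuple(true_toks)))
        doc_id = f"synth-{di:05d}"
        obs_docs.append(Document(doc_id=doc_id, sentences=tuple(obs_sents)))
        true_docs.append(Document(doc_id=doc_id, sentences=tuple(true_sents)))
    return LabeledCorpus(tuple(obs_docs)), LabeledCorpus(tuple(true_docs))
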