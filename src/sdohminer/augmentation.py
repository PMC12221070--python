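"""Template-based synthetic-sentence augmentation.

Rare entity types are over-sampled by instantiating slotted sentence
templates with surface-form variants drawn from an entity-variation
lexicon (corpus-derived rare mentions plus curated additions), then
embedding the resulting sentence sets at random positions inside host
documents.  The training regime uses entity-dense templates; the
generalization regime derives sparser templates with permuted slot orders
to probe overfitting.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import yaml

from .corpus import Document, LabeledCorpus, Sentence, Token

_DATA_DIR = Path(__file__).parent / "data"
_SLOT_RE = re.compile(r"^\{([A-Za-z_]+)\}$")

CURATED = "curated"
CORPUS_RARE = "corpus_rare"


@dataclass(frozen=True)
class Template:
    """Ordered mix of literal 'O' tokens and entity-type slots."""

    template_id: str
    elements: tuple[tuple[str, str], ...]  # ("lit", token) | ("slot", type)

    def __post_init__(self) -> None:
        if not any(kind == "slot" for kind, _ in self.elements):
            raise ValueError(f"template {self.template_id!r} has no entity slot")

    @property
    def slot_types(self) -> tuple[str, ...]:
        return tuple(v for kind, v in self.elements if kind == "slot")

    @property
    def o_proportion(self) -> float:
        n_lit = sum(1 for kind, _ in self.elements if kind == "lit")
        return n_lit / len(self.elements)

    @classmethod
    def from_text(cls, template_id: str, text: str) -> "Template":
        """Parse a whitespace-tokenized string with ``{Type}`` slot markers."""
        elements = []
        for tok in text.split():
            m = _SLOT_RE.match(tok)
            if m:
                elements.append(("slot", m.group(1)))
            else:
                elements.append(("lit", tok))
        return cls(template_id=template_id, elements=tuple(elements))


def load_templates(path: Union[str, Path]) -> list[Template]:
    with Path(path).open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return [Template.from_text(t["id"], t["text"]) for t in raw["templates"]]


def default_training_templates() -> list[Template]:
    return load_templates(_DATA_DIR / "templates_training.yaml")


@dataclass(frozen=True)
class VariationLexicon:
    """Per-type surface variants, each tagged with its source."""

    entries: Mapping[str, tuple[tuple[str, str], ...]]  # type -> ((surface, tag), ...)

    def variants(self, entity_type: str, curated_only: bool = False) -> list[str]:
        pool = self.entries.get(entity_type, ())
        out = [s for s, tag in pool if not curated_only or tag == CURATED]
        if not out:
            which = "curated " if curated_only else ""
            raise KeyError(
                f"no {which}variants for entity type {entity_type!r}"
            )
        return out

    @classmethod
    def from_yaml(cls, path: Union[str, Path], tag: str = CURATED):
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        entries = {
            etype: tuple((str(s), tag) for s in variants)
            for etype, variants in raw["entries"].items()
        }
        return cls(entries=entries)


def default_curated_lexicon() -> VariationLexicon:
    return VariationLexicon.from_yaml(_DATA_DIR / "lexicon_curated.yaml")


def build_variation_lexicon(
    corpus: LabeledCorpus,
    curated: VariationLexicon,
    rare_threshold: float = 0.01,
) -> VariationLexicon:
    """Union curated variants with corpus surface forms of rare types.

    A type is rare when its share of all non-'O' mentions falls below
    ``rare_threshold``.  Deduplication is case-insensitive; curated entries
    win on collision so their tag is kept.
    """
    from .entity_analysis import collapse_mentions

    mention_counts: Counter[str] = Counter()
    surfaces: dict[str, list[str]] = {}
    for d in corpus.documents:
        for m in collapse_mentions(d):
            mention_counts[m.entity_type] += 1
            surfaces.setdefault(m.entity_type, []).append(m.surface)
    total = sum(mention_counts.values())

    merged: dict[str, list[tuple[str, str]]] = {
        etype: list(pool) for etype, pool in curated.entries.items()
    }
    if total:
        for etype, count in mention_counts.items():
            if count / total < rare_threshold:
                pool = merged.setdefault(etype, [])
                seen = {s.lower() for s, _ in pool}
                for surf in surfaces[etype]:
                    if surf.lower() not in seen:
                        pool.append((surf, CORPUS_RARE))
                        seen.add(surf.lower())
    return VariationLexicon(
        entries={k: tuple(v) for k, v in merged.items()}
    )


@dataclass(frozen=True)
class AugmentationConfig:
    n_sets: int = 3000
    split: tuple[int, int] = (1500, 1500)  # (full lexicon, curated only)
    regime: str = "training"  # training | generalization
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.split) != self.n_sets:
            raise ValueError(
                f"split {self.split} does not sum to n_sets {self.n_sets}"
            )
        if self.regime not in ("training", "generalization"):
            raise ValueError(f"unknown regime {self.regime!r}")


@dataclass(frozen=True)
class SyntheticSet:
    """One instantiation of every template, under a shared identifier."""

    set_id: str
    sentences: tuple[Sentence, ...]
    source: str  # "full" | "curated"

    @property
    def n_tokens(self) -> int:
        return sum(len(s) for s in self.sentences)


def _instantiate(
    template: Template,
    lexicon: VariationLexicon,
    rng: np.random.Generator,
    curated_only: bool,
) -> Sentence:
    toks: list[Token] = []
    for kind, value in template.elements:
        if kind == "lit":
            toks.append(Token(text=value, label="O"))
        else:
            pool = lexicon.variants(value, curated_only=curated_only)
            surface = pool[int(rng.integers(len(pool)))]
            words = surface.split()
            toks.append(Token(text=words[0], label=f"B-{value}"))
            toks.extend(
                Token(text=w, label=f"I-{value}") for w in words[1:]
            )
    return Sentence(tuple(toks))


def generate_synthetic_sets(
    templates: Sequence[Template],
    lexicon: VariationLexicon,
    cfg: AugmentationConfig = AugmentationConfig(),
) -> list[SyntheticSet]:
    """Emit ``cfg.n_sets`` uniquely identified synthetic sentence sets.

    The first ``split[0]`` sets sample variants from the full lexicon
    (corpus-rare + curated); the remaining ``split[1]`` from curated entries
    alone.  Variant choice is uniform over the eligible pool and
    deterministic under ``cfg.seed``.
    """
    for t in templates:
        for etype in t.slot_types:
            lexicon.variants(etype)  # raises if uncovered
            lexicon.variants(etype, curated_only=True)
    rng = np.random.default_rng(cfg.seed)
    n_full, _ = cfg.split
    sets = []
    for i in range(cfg.n_sets):
        curated_only = i >= n_full
        sentences = tuple(
            _instantiate(t, lexicon, rng, curated_only) for t in templates
        )
        sets.append(
            SyntheticSet(
                set_id=f"synset-{cfg.regime}-{i:05d}",
                sentences=sentences,
                source="curated" if curated_only else "full",
            )
        )
    return sets


def variant_usage(sets: Iterable[SyntheticSet]) -> Counter:
    """Per-(type, surface) usage counts, for auditing sampling skew."""
    counts: Counter[tuple[str, str]] = Counter()
    for st in sets:
        for sent in st.sentences:
            run_type, run_words = None, []
            for t in list(sent.tokens) + [Token(text="_", label="O")]:
                if t.label.startswith("B-") or t.label == "O":
                    if run_type is not None:
                        counts[(run_type, " ".join(run_words))] += 1
                    run_type, run_words = None, []
                if t.label.startswith("B-"):
                    run_type, run_words = t.label[2:], [t.text]
                elif t.label.startswith("I-"):
                    run_words.append(t.text)
    return counts


def embed_sets(
    corpus: LabeledCorpus,
    sets: Sequence[SyntheticSet],
    seed: int = 0,
) -> LabeledCorpus:
    """Insert each set's sentences, contiguous and in order, at a uniformly
    random sentence position of a uniformly random host document.

    Original tokens survive unchanged and in relative order; host documents
    are marked ``augmented`` and record the set identifiers they carry.
    """
    if not corpus.documents:
        raise ValueError("cannot embed into an empty corpus")
    rng = np.random.default_rng(seed)
    sent_lists = [list(d.sentences) for d in corpus.documents]
    new_set_ids: list[list[str]] = [[] for _ in corpus.documents]
    # track original-sentence slots so inserts land between original sentences
    for st in sets:
        di = int(rng.integers(len(sent_lists)))
        pos = int(rng.integers(len(sent_lists[di]) + 1))
        sent_lists[di][pos:pos] = list(st.sentences)
        new_set_ids[di].append(st.set_id)
    docs = []
    for d, sl, ids in zip(corpus.documents, sent_lists, new_set_ids):
        if ids:
            docs.append(
                replace(
                    d,
                    sentences=tuple(sl),
                    provenance="augmented",
                    set_ids=d.set_ids + tuple(ids),
                )
            )
        else:
            docs.append(replace(d, sentences=tuple(sl)))
    return LabeledCorpus(tuple(docs))


_FILLERS = (
    "the", "patient", "report", "notes", "that", "was",
    "documented", "during", "clinical", "review",
)


def make_generalization_templates(base: Sequence[Template]) -> list[Template]:
    """Derive evaluation-regime templates from the training templates.

    The derived set has (a) a strictly higher literal-'O' proportion than
    every base template, (b) slot orders differing from every base order,
    and (c) the Gender slot absent from at least one template — gender is
    already frequent pre-augmentation, so at least one evaluation structure
    omits it.
    """
    base_orders = {t.slot_types for t in base}
    max_o = max(t.o_proportion for t in base)
    out = []
    gender_dropped = False
    filler_idx = 0
    for t in base:
        slots = list(t.slot_types)[::-1]
        if not gender_dropped and "Gender" in slots:
            slots.remove("Gender")
            gender_dropped = True
        while tuple(slots) in base_orders:
            slots = slots[1:] + slots[:1]
        n_slots = len(slots)
        # choose n_lit so n_lit / (n_lit + n_slots) > max_o
        n_lit = math.floor(max_o / (1.0 - max_o) * n_slots) + 1
        elements: list[tuple[str, str]] = []
        per_slot = [n_lit // n_slots] * n_slots
        for i in range(n_lit % n_slots):
            per_slot[i] += 1
        for k, stype in zip(per_slot, slots):
            for _ in range(k):
                elements.append(("lit", _FILLERS[filler_idx % len(_FILLERS)]))
                filler_idx += 1
            elements.append(("slot", stype))
        out.append(
            Template(template_id=f"{t.template_id}-gen", elements=tuple(elements))
        )
    return out
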