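"""Entity-type schema, BIO expansion, label refinement, dual-tagger merge.

The refined inventory groups the raw outputs of two pre-trained clinical
taggers into 26 social/behavioral/clinical core types plus the non-entity
class 'O' (27 in total), which BIO-expands to 53 training labels.  The
many-to-one refinement map collapses closely related source types (e.g.
several disease labels into ``Condition``) and demotes out-of-scope types
to 'O'; it ships as an editable YAML so a different mapping can be
dropped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import yaml

from .corpus import LabeledCorpus, Token

_DATA_DIR = Path(__file__).parent / "data"

#: The 26 refined core entity types, in canonical order.
DEFAULT_CORE_TYPES: tuple[str, ...] = (
    "Access_To_Care",
    "Age",
    "Condition",
    "Diet",
    "Disability",
    "Education",
    "Employment",
    "Exercise",
    "Family_Member",
    "Gender",
    "Geographic_Entity",
    "Housing",
    "Income",
    "Insurance_Status",
    "Language",
    "Marital_Status",
    "Mental_Health",
    "Race_Ethnicity",
    "Severity",
    "Sexual_Orientation",
    "Social_Support",
    "Spiritual_Beliefs",
    "Substance",
    "Treatment",
    "Vaccine",
    "Violence_Or_Abuse",
)


def normalize_type_name(name: str) -> str:
    """Canonical form: spaces -> underscores; comparisons are case-sensitive."""
    return "_".join(name.split())


@dataclass(frozen=True)
class LabelSchema:
    """Core entity types plus 'O', with a derived BIO expansion."""

    core_types: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.core_types)) != len(self.core_types):
            dupes = sorted(
                {t for t in self.core_types if self.core_types.count(t) > 1}
            )
            raise ValueError(f"duplicate core types: {dupes}")
        for t in self.core_types:
            if t == "O":
                raise ValueError("'O' is implicit, not a core type")

    @property
    def expanded_labels(self) -> tuple[str, ...]:
        return expand_bio(self)

    def __contains__(self, core_type: str) -> bool:
        return core_type in self.core_types


def default_schema() -> LabelSchema:
    """The shipped 26-type refined schema (27 classes counting 'O')."""
    return LabelSchema(core_types=DEFAULT_CORE_TYPES)


def expand_bio(schema: LabelSchema) -> tuple[str, ...]:
    """'O' first, then B-/I- pairs in core-type order: 2n+1 labels."""
    out = ["O"]
    for t in schema.core_types:
        out.append(f"B-{t}")
        out.append(f"I-{t}")
    return tuple(out)


@dataclass(frozen=True)
class RefinementMap:
    """Many-to-one map from source core types to refined core types or 'O'."""

    mapping: Mapping[str, str]
    unmapped_policy: str = "error"  # error | to_O

    def __post_init__(self) -> None:
        if self.unmapped_policy not in ("error", "to_O"):
            raise ValueError(f"unknown unmapped_policy {self.unmapped_policy!r}")

    def target(self, source_type: str) -> str:
        if source_type in self.mapping:
            return self.mapping[source_type]
        if self.unmapped_policy == "to_O":
            return "O"
        raise KeyError(source_type)

    @classmethod
    def from_yaml(cls, path: Union[str, Path], unmapped_policy: str = "error"):
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        mapping = {
            normalize_type_name(k): normalize_type_name(str(v)) if v != "O" else "O"
            for k, v in raw["mapping"].items()
        }
        return cls(mapping=mapping, unmapped_policy=unmapped_policy)


def default_refinement_map() -> RefinementMap:
    """The shipped source-to-refined map (editable YAML in ``data/``)."""
    return RefinementMap.from_yaml(_DATA_DIR / "refinement_map.yaml")


def refine_labels(corpus: LabeledCorpus, rmap: RefinementMap) -> LabeledCorpus:
    """Rewrite every token label into the refined schema.

    The BIO prefix is preserved; source types mapping to 'O' lose their
    prefix entirely.  Token text, order, confidences and sentence structure
    are untouched.  Unmapped labels raise (listing all offenders) under the
    ``error`` policy.
    """
    if rmap.unmapped_policy == "error":
        missing = sorted(
            {
                lab[2:]
                for lab in corpus.labels_used()
                if lab != "O" and lab[2:] not in rmap.mapping
            }
        )
        if missing:
            raise KeyError(f"source types not in refinement map: {missing}")

    def rewrite(t: Token) -> Token:
        if t.label == "O":
            return t
        tgt = rmap.target(t.label[2:])
        if tgt == "O":
            return replace(t, label="O")
        return replace(t, label=t.label[:2] + tgt)

    return corpus.map_tokens(rewrite)


@dataclass(frozen=True)
class MergePolicy:
    """Which entity types a secondary tagger is trusted over the primary for.

    The default overrides reflect a secondary clinical-trials tagger being
    more reliable on patient age and supplying vaccination status, which the
    primary social-determinants tagger lacks.
    """

    override_types: frozenset[str] = frozenset({"Age", "Vaccine"})


class AlignmentError(ValueError):
    pass


def merge_model_annotations(
    primary: LabeledCorpus,
    secondary: LabeledCorpus,
    policy: MergePolicy = MergePolicy(),
) -> LabeledCorpus:
    """Token-wise merge of two taggers' outputs over the same text.

    Where the secondary tagger assigns a non-'O' label whose type is in
    ``policy.override_types``, its label and confidence replace the
    primary's; everywhere else the primary wins.  A secondary 'O' never
    erases a primary label (the substitution is additive).
    """
    if len(primary.documents) != len(secondary.documents):
        raise AlignmentError(
            f"document count differs: {len(primary.documents)} vs "
            f"{len(secondary.documents)}"
        )
    docs = []
    for d1, d2 in zip(primary.documents, secondary.documents):
        t1 = list(d1.iter_tokens())
        t2 = list(d2.iter_tokens())
        if len(t1) != len(t2):
            raise AlignmentError(
                f"token count differs in document {d1.doc_id!r}: "
                f"{len(t1)} vs {len(t2)}"
            )
        for i, (a, b) in enumerate(zip(t1, t2)):
            if a.text != b.text:
                raise AlignmentError(
                    f"token text diverges in document {d1.doc_id!r} at "
                    f"position {i}: {a.text!r} vs {b.text!r}"
                )
        merged_flat = [
            b
            if (b.label != "O" and b.label[2:] in policy.override_types)
            else a
            for a, b in zip(t1, t2)
        ]
        # re-impose the primary document's sentence structure
        sents = []
        pos = 0
        from .corpus import Sentence

        for s in d1.sentences:
            sents.append(Sentence(tuple(merged_flat[pos : pos + len(s)])))
            pos += len(s)
        docs.append(replace(d1, sentences=tuple(sents)))
    return LabeledCorpus(tuple(docs))
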