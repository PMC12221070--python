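"""Rule-based natural-language inference over extracted entity mentions.

Each entity type carries one statement (e.g. "Has medical insurance") with
an entailment and a contradiction term list.  A mention's surface string is
matched case-insensitively against both lists with word boundaries at both
phrase ends; an entailment hit yields Entailment, a contradiction hit
Contradiction, neither NotApplicable.  Aggregation reports, per statement,
the percent entailment vs. contradiction over applicable mentions only —
NotApplicable outcomes are noise-prone and excluded.  Restricted mode
matches a statement only against mentions of its own entity type; full
mode scans every mention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from .entity_analysis import EntityMention

_DATA_DIR = Path(__file__).parent / "data"

ENTAILMENT = "Entailment"
CONTRADICTION = "Contradiction"
NOT_APPLICABLE = "NotApplicable"


def normalize_term(term: str) -> str:
    return " ".join(term.lower().split())


def expand_lexicon(
    terms: Sequence[str],
    synonym_source: Optional[Mapping[str, Sequence[str]]] = None,
) -> list[str]:
    """Normalize, deduplicate, and extend terms with their synonyms.

    ``synonym_source`` maps a term to its synonyms (a small YAML resource
    ships with the package; any mapping works).  Expansion is idempotent:
    synonyms-of-synonyms are not chased.
    """
    if not terms:
        raise ValueError("term list must be non-empty")
    syn = {
        normalize_term(k): [normalize_term(s) for s in v]
        for k, v in (synonym_source or {}).items()
    }
    out: list[str] = []
    seen: set[str] = set()

    def add(t: str) -> None:
        if t and t not in seen:
            seen.add(t)
            out.append(t)

    for raw in terms:
        t = normalize_term(raw)
        add(t)
        for s in syn.get(t, []):
            add(s)
    return out


def load_synonyms(path: Union[str, Path, None] = None) -> dict[str, list[str]]:
    with Path(path or _DATA_DIR / "synonyms.yaml").open(encoding="utf-8") as fh:
        return yaml.safe_load(fh)["synonyms"]


@dataclass(frozen=True)
class NLIStatement:
    statement_id: str
    entity_type: str
    text: str
    entail_terms: tuple[str, ...]
    contradict_terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.entail_terms or not self.contradict_terms:
            raise ValueError(
                f"statement {self.statement_id!r}: both term lists must be non-empty"
            )
        clash = set(self.entail_terms) & set(self.contradict_terms)
        if clash:
            raise ValueError(
                f"statement {self.statement_id!r}: term(s) in both lists after "
                f"normalization: {sorted(clash)} — curate the lexicons"
            )


def make_statement(
    statement_id: str,
    entity_type: str,
    text: str,
    entail: Sequence[str],
    contradict: Sequence[str],
    synonym_source: Optional[Mapping[str, Sequence[str]]] = None,
) -> NLIStatement:
    """Build a statement with expanded, validated lexicons."""
    return NLIStatement(
        statement_id=statement_id,
        entity_type=entity_type,
        text=text,
        entail_terms=tuple(expand_lexicon(entail, synonym_source)),
        contradict_terms=tuple(expand_lexicon(contradict, synonym_source)),
    )


def load_statements(
    path: Union[str, Path, None] = None,
    synonym_source: Optional[Mapping[str, Sequence[str]]] = None,
) -> list[NLIStatement]:
    with Path(path or _DATA_DIR / "statements.yaml").open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return [
        make_statement(
            s["id"], s["entity_type"], s["text"], s["entail"], s["contradict"],
            synonym_source,
        )
        for s in raw["statements"]
    ]


@dataclass(frozen=True)
class NLIResult:
    mention: EntityMention
    statement_id: str
    outcome: str
    matched_term: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.outcome == NOT_APPLICABLE) != (self.matched_term is None):
            raise ValueError("matched_term present iff outcome is applicable")


def _term_pattern(term: str) -> re.Pattern:
    words = [re.escape(w) for w in term.split()]
    return re.compile(r"(?<!\w)" + r"\s+".join(words) + r"(?!\w)", re.IGNORECASE)


def _find_matches(surface: str, terms: Iterable[str]) -> list[str]:
    return [t for t in terms if _term_pattern(t).search(surface)]


def classify_entity(mention: EntityMention, stmt: NLIStatement) -> NLIResult:
    """Match the mention surface against the statement's two lexicons.

    If both lists match, the longest matched term wins; on an exact length
    tie the contradiction reading is kept (the conservative choice — it
    avoids overstating positive representation).
    """
    surface = " ".join(mention.surface.split())
    e_hits = _find_matches(surface, stmt.entail_terms)
    c_hits = _find_matches(surface, stmt.contradict_terms)
    best_e = max(e_hits, key=len, default=None)
    best_c = max(c_hits, key=len, default=None)
    if best_e is None and best_c is None:
        return NLIResult(mention, stmt.statement_id, NOT_APPLICABLE)
    if best_c is None or (best_e is not None and len(best_e) > len(best_c)):
        return NLIResult(mention, stmt.statement_id, ENTAILMENT, best_e)
    return NLIResult(mention, stmt.statement_id, CONTRADICTION, best_c)


def aggregate(
    mentions: Sequence[EntityMention],
    statements: Sequence[NLIStatement],
    mode: str = "restricted",
) -> pd.DataFrame:
    """Per-statement entailment/contradiction percentages.

    Percentages are over applicable outcomes only, so they sum to 100 per
    row; statements with zero applicable outcomes are absent from the table
    rather than reported as 0/0.
    """
    if mode not in ("restricted", "full"):
        raise ValueError(f"unknown mode {mode!r}")
    if not mentions:
        raise ValueError("no mentions to aggregate")
    rows = []
    for stmt in statements:
        pool = (
            [m for m in mentions if m.entity_type == stmt.entity_type]
            if mode == "restricted"
            else mentions
        )
        n_e = n_c = 0
        for m in pool:
            res = classify_entity(m, stmt)
            if res.outcome == ENTAILMENT:
                n_e += 1
            elif res.outcome == CONTRADICTION:
                n_c += 1
        n = n_e + n_c
        if n == 0:
            continue
        rows.append(
            {
                "statement_id": stmt.statement_id,
                "statement": stmt.text,
                "entity_type": stmt.entity_type,
                "n_entailment": n_e,
                "n_contradiction": n_c,
                "pct_entailment": 100.0 * n_e / n,
                "pct_contradiction": 100.0 * n_c / n,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "statement_id", "statement", "entity_type",
            "n_entailment", "n_contradiction",
            "pct_entailment", "pct_contradiction",
        ],
    ).set_index("statement_id")
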