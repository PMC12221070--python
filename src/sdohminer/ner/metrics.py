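"""Token-level evaluation: per-class F1, macro F1 (incl./excl. 'O'),
one-vs-one and one-vs-rest multiclass ROC AUC, plus an optional
span-level report.

F1 is computed per BIO label (token level), since B- and I- sub-labels are
scored separately; macro averages are unweighted over the classes present
in the reference.  OVO AUC averages, over every ordered pair of supported
classes (i, j), the AUC of the class-i score separating class-i from
class-j samples; OVR AUC averages the one-vs-rest AUC over supported
classes.  Ties in scores are handled by mid-rank statistics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.stats import rankdata

from ..corpus import LabeledCorpus


@dataclass
class MetricsReport:
    per_class_f1: dict[str, float]
    macro_f1: float
    macro_f1_excl_O: float  # NaN when no entity class is present
    macro_auc_ovo: float
    macro_auc_ovr: float
    skipped_classes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "per_class_f1": self.per_class_f1,
            "macro_f1": self.macro_f1,
            "macro_f1_excl_O": self.macro_f1_excl_O,
            "macro_auc_ovo": self.macro_auc_ovo,
            "macro_auc_ovr": self.macro_auc_ovr,
            "skipped_classes": list(self.skipped_classes),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def _binary_auc(scores: np.ndarray, positives: np.ndarray) -> float:
    """Mann-Whitney AUC with mid-ranks for ties."""
    n_pos = int(positives.sum())
    n_neg = len(positives) - n_pos
    if n_pos == 0 or n_neg == 0:
        return np.nan
    ranks = rankdata(scores)
    return (ranks[positives].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _gold_labels(gold: Union[LabeledCorpus, Sequence[str]]) -> list[str]:
    if isinstance(gold, LabeledCorpus):
        return [t.label for t in gold.iter_tokens()]
    return list(gold)


def evaluate(
    pred_scores: np.ndarray,
    gold: Union[LabeledCorpus, Sequence[str]],
    label_list: Sequence[str],
    row_sum_tol: float = 1e-6,
) -> MetricsReport:
    """Score a (n_tokens, n_labels) probability matrix against reference labels.

    Classes absent from the reference are skipped from every average and
    listed on the report.  ``macro_f1_excl_O`` is NaN (with a warning) when
    the reference contains no entity class.
    """
    labels = list(label_list)
    gold_labs = _gold_labels(gold)
    scores = np.asarray(pred_scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != len(labels):
        raise ValueError(
            f"score matrix shape {scores.shape} does not match "
            f"{len(labels)} labels"
        )
    if scores.shape[0] != len(gold_labs):
        raise ValueError(
            f"{scores.shape[0]} score rows vs {len(gold_labs)} gold tokens"
        )
    bad = np.abs(scores.sum(axis=1) - 1.0) > row_sum_tol
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} score row(s) do not sum to 1 "
            f"(tolerance {row_sum_tol})"
        )
    unknown = set(gold_labs) - set(labels)
    if unknown:
        raise ValueError(f"gold labels outside label list: {sorted(unknown)}")

    y = np.asarray([labels.index(g) for g in gold_labs])
    pred = scores.argmax(axis=1)
    present = [i for i in range(len(labels)) if (y == i).any()]
    skipped = tuple(labels[i] for i in range(len(labels)) if i not in present)

    per_class: dict[str, float] = {}
    for i in present:
        tp = int(((pred == i) & (y == i)).sum())
        fp = int(((pred == i) & (y != i)).sum())
        fn = int(((pred != i) & (y == i)).sum())
        per_class[labels[i]] = (
            2.0 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        )

    macro_f1 = float(np.mean(list(per_class.values()))) if per_class else np.nan
    entity_f1 = [v for k, v in per_class.items() if k != "O"]
    if entity_f1:
        macro_f1_excl_O = float(np.mean(entity_f1))
    else:
        warnings.warn("no entity class present in gold; macro_f1_excl_O is NaN")
        macro_f1_excl_O = np.nan

    ovr = [
        a
        for i in present
        if not np.isnan(a := _binary_auc(scores[:, i], y == i))
    ]
    macro_auc_ovr = float(np.mean(ovr)) if ovr else np.nan

    ovo_vals = []
    for i in present:
        for j in present:
            if i == j:
                continue
            sel = (y == i) | (y == j)
            ovo_vals.append(_binary_auc(scores[sel, i], y[sel] == i))
    macro_auc_ovo = float(np.mean(ovo_vals)) if ovo_vals else np.nan

    return MetricsReport(
        per_class_f1=per_class,
        macro_f1=macro_f1,
        macro_f1_excl_O=macro_f1_excl_O,
        macro_auc_ovo=macro_auc_ovo,
        macro_auc_ovr=macro_auc_ovr,
        skipped_classes=skipped,
    )


def _spans(labels: Sequence[str]) -> set[tuple[str, int, int]]:
    out = set()
    start, cur = None, None
    for i, lab in enumerate(list(labels) + ["O"]):
        if lab.startswith("I-") and cur == lab[2:]:
            continue
        if cur is not None:
            out.add((cur, start, i))
        if lab.startswith("B-") or lab.startswith("I-"):
            cur, start = lab[2:], i
        else:
            cur = None
    return out


def span_f1_report(
    pred_labels: Sequence[str], gold: Union[LabeledCorpus, Sequence[str]]
) -> dict[str, float]:
    """Exact-span micro precision/recall/F1 (an extra report beside the
    primary token-level scores)."""
    gold_labs = _gold_labels(gold)
    if len(pred_labels) != len(gold_labs):
        raise ValueError("prediction/gold length mismatch")
    ps, gs = _spans(pred_labels), _spans(gold_labs)
    tp = len(ps & gs)
    prec = tp / len(ps) if ps else 0.0
    rec = tp / len(gs) if gs else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return {"precision": prec, "recall": rec, "f1": f1}
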