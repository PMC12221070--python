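"""End-to-end orchestration: ingest -> merge -> refine -> filter -> augment
-> segment -> train -> evaluate -> analyze -> nli.

Documents are partitioned into three disjoint subset roles mirroring the
study design: a human-reviewed training subset, an augmented training
subset, and an augmented generalization-evaluation subset (default sizes
99/402/208, fully overridable), with an 80/20 document-level split of the
combined training material.  Every run emits a manifest carrying a config
hash, the seeds used, and per-stage counters so reruns are auditable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from . import augmentation as aug
from . import entity_analysis as ana
from . import filtration as filt
from . import nli_rules as nli
from .corpus import LabeledCorpus, repair_bio
from .corpus_io import read_conll, segment_document
from .label_schema import (
    MergePolicy,
    default_refinement_map,
    default_schema,
    merge_model_annotations,
    refine_labels,
)
from .ner import TrainConfig, evaluate, split_documents, train
from .synthetic_corpus import CorpusSpec, generate_corpus

ALL_STAGES = (
    "ingest", "merge", "refine", "filter", "augment",
    "segment", "train", "evaluate", "analyze", "nli",
)


@dataclass(frozen=True)
class RunConfig:
    stages: tuple[str, ...] = ALL_STAGES
    conll_path: Optional[str] = None
    secondary_path: Optional[str] = None
    synth_spec: Optional[CorpusSpec] = None  # used when conll_path is None
    subset_sizes: tuple[int, int, int] = (99, 402, 208)
    train_split: float = 0.8
    confidence_floor: float = 0.90
    apply_refinement: bool = False  # True when labels use the source inventory
    n_sets: int = 3000
    set_split: tuple[int, int] = (1500, 1500)
    max_segment_tokens: int = 512
    train_cfg: TrainConfig = field(default_factory=TrainConfig)
    top_k_trigrams: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if not (0.0 < self.train_split < 1.0):
            raise ValueError("train_split must be in (0, 1)")
        if any(s < 0 for s in self.subset_sizes):
            raise ValueError("subset sizes must be non-negative")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), default=str, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    artifacts: dict
    manifest: dict


class MissingArtifactError(RuntimeError):
    pass


def _need(artifacts: dict, key: str, stage: str):
    if key not in artifacts:
        raise MissingArtifactError(
            f"stage {stage!r} requires artifact {key!r}; enable the stage "
            f"producing it"
        )
    return artifacts[key]


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    stages = set(cfg.stages)
    artifacts: dict = {}
    counters: dict = {}
    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": list(cfg.stages),
        "counters": counters,
    }
    schema = default_schema()

    if "ingest" in stages:
        if cfg.conll_path is not None:
            corpus = read_conll(cfg.conll_path)
        else:
            spec = cfg.synth_spec or CorpusSpec(
                n_documents=sum(cfg.subset_sizes), seed=cfg.seed
            )
            corpus, truth = generate_corpus(spec)
            artifacts["truth"] = truth
        corpus = repair_bio(corpus, warn=False)  # noisy taggers emit dangling I-
        artifacts["corpus"] = corpus
        counters["ingest"] = {
            "documents": len(corpus),
            "sentences": corpus.n_sentences,
            "tokens": corpus.n_tokens,
        }

    if "merge" in stages and cfg.secondary_path is not None:
        corpus = _need(artifacts, "corpus", "merge")
        secondary = read_conll(cfg.secondary_path)
        artifacts["corpus"] = merge_model_annotations(
            corpus, secondary, MergePolicy()
        )
        counters["merge"] = {"secondary_documents": len(secondary)}

    if "refine" in stages and cfg.apply_refinement:
        corpus = _need(artifacts, "corpus", "refine")
        artifacts["corpus"] = refine_labels(corpus, default_refinement_map())
        counters["refine"] = {"labels": len(artifacts["corpus"].labels_used())}

    # subset partition (document order; roles disjoint by construction)
    if any(s in stages for s in ("filter", "augment", "train", "evaluate")):
        corpus = _need(artifacts, "corpus", "filter")
        s1n, s2n, s3n = cfg.subset_sizes
        if len(corpus.documents) < s1n + s2n + s3n:
            raise ValueError(
                f"corpus has {len(corpus.documents)} documents; "
                f"subset sizes {cfg.subset_sizes} need {s1n + s2n + s3n}"
            )
        docs = corpus.documents
        sub1 = LabeledCorpus(docs[:s1n])
        sub2 = LabeledCorpus(docs[s1n : s1n + s2n])
        sub3 = LabeledCorpus(docs[s1n + s2n : s1n + s2n + s3n])

    if "filter" in stages:
        def _clean(c: LabeledCorpus, drop_o: bool) -> tuple[LabeledCorpus, dict]:
            after_floor = filt.apply_confidence_floor(c, cfg.confidence_floor)
            n_floor = sum(
                1
                for a, b in zip(c.iter_tokens(), after_floor.iter_tokens())
                if a.label != b.label
            )
            after_num = filt.demote_numeric_nonage(after_floor)
            n_num = sum(
                1
                for a, b in zip(
                    after_floor.iter_tokens(), after_num.iter_tokens()
                )
                if a.label != b.label
            )
            out = (
                filt.drop_all_O_sentences(after_num) if drop_o else after_num
            )
            return out, {
                "tokens_demoted_confidence": n_floor,
                "tokens_demoted_numeric": n_num,
                "sentences_dropped": after_num.n_sentences - out.n_sentences,
            }

        sub2, c2 = _clean(sub2, drop_o=True)  # training subset
        sub3, c3 = _clean(sub3, drop_o=False)  # evaluation subset
        counters["filter"] = {"training_subset": c2, "generalization_subset": c3}

    if "augment" in stages:
        templates = aug.default_training_templates()
        curated = aug.default_curated_lexicon()
        lexicon = aug.build_variation_lexicon(
            _need(artifacts, "corpus", "augment"), curated
        )
        train_sets = aug.generate_synthetic_sets(
            templates,
            lexicon,
            aug.AugmentationConfig(
                n_sets=cfg.n_sets, split=cfg.set_split,
                regime="training", seed=cfg.seed,
            ),
        )
        before = sub2.n_tokens
        sub2 = aug.embed_sets(sub2, train_sets, seed=cfg.seed)
        gen_templates = aug.make_generalization_templates(templates)
        gen_sets = aug.generate_synthetic_sets(
            gen_templates,
            lexicon,
            aug.AugmentationConfig(
                n_sets=cfg.n_sets, split=cfg.set_split,
                regime="generalization", seed=cfg.seed + 1,
            ),
        )
        before3 = sub3.n_tokens
        sub3 = aug.embed_sets(sub3, gen_sets, seed=cfg.seed + 1)
        counters["augment"] = {
            "training_sets": len(train_sets),
            "generalization_sets": len(gen_sets),
            "training_tokens_added": sub2.n_tokens - before,
            "generalization_tokens_added": sub3.n_tokens - before3,
        }
        artifacts["variant_usage"] = aug.variant_usage(train_sets)

    if any(s in stages for s in ("segment", "train", "evaluate")):
        training_corpus = LabeledCorpus(sub1.documents + sub2.documents)
        artifacts["training_corpus"] = training_corpus
        artifacts["generalization_corpus"] = sub3

    if "segment" in stages:
        segments = [
            seg
            for d in artifacts["training_corpus"].documents
            for seg in segment_document(d, cfg.max_segment_tokens)
        ]
        artifacts["segments"] = segments
        counters["segment"] = {
            "segments": len(segments),
            "tokens": sum(len(s) for s in segments),
        }

    label_list = list(schema.expanded_labels)
    if "train" in stages:
        tr, opt_test = split_documents(
            artifacts["training_corpus"], cfg.train_split, seed=cfg.seed
        )
        artifacts["optimization_test_corpus"] = opt_test
        tagger = train(tr, label_list, cfg.train_cfg)
        artifacts["tagger"] = tagger
        counters["train"] = {
            "train_documents": len(tr),
            "test_documents": len(opt_test),
            "final_loss": tagger.loss_history[-1] if tagger.loss_history else None,
        }

    if "evaluate" in stages:
        tagger = _need(artifacts, "tagger", "evaluate")
        reports = {}
        for name, c in (
            ("optimization_test", _need(artifacts, "optimization_test_corpus", "evaluate")),
            ("generalization", _need(artifacts, "generalization_corpus", "evaluate")),
        ):
            scores = tagger.predict_scores(c)
            reports[name] = evaluate(scores, c, label_list)
        artifacts["metrics"] = reports
        counters["evaluate"] = {
            name: {
                "macro_f1": r.macro_f1,
                "macro_f1_excl_O": r.macro_f1_excl_O,
                "macro_auc_ovo": r.macro_auc_ovo,
                "macro_auc_ovr": r.macro_auc_ovr,
            }
            for name, r in reports.items()
        }

    if "analyze" in stages:
        corpus = _need(artifacts, "corpus", "analyze")
        _, hist = ana.entity_richness(corpus)
        freq = ana.frequency_table(corpus)
        trig = ana.trigram_frequencies(corpus, top_k=cfg.top_k_trigrams)
        artifacts["analysis"] = {
            "richness_histogram": hist,
            "frequency_table": freq,
            "trigram_table": trig,
        }
        counters["analyze"] = {
            "entity_types": int(freq.shape[0]),
            "trigrams": int(trig.shape[0]),
        }

    if "nli" in stages:
        corpus = _need(artifacts, "corpus", "nli")
        statements = nli.load_statements(synonym_source=nli.load_synonyms())
        mentions = ana.all_mentions(corpus)
        artifacts["nli"] = {
            mode: nli.aggregate(mentions, statements, mode=mode)
            for mode in ("restricted", "full")
        }
        counters["nli"] = {
            mode: int(df.shape[0]) for mode, df in artifacts["nli"].items()
        }

    return PipelineResult(artifacts=artifacts, manifest=manifest)
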