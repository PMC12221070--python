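"""Template instantiation, lexicon building, set generation, embedding."""

import numpy as np
import pytest

from sdohminer.augmentation import (
    CORPUS_RARE,
    CURATED,
    AugmentationConfig,
    Template,
    VariationLexicon,
    build_variation_lexicon,
    default_curated_lexicon,
    default_training_templates,
    embed_sets,
    generate_synthetic_sets,
    make_generalization_templates,
    variant_usage,
)
from sdohminer.corpus import validate_bio
from sdohminer.entity_analysis import all_mentions

from conftest import make_corpus, random_bio_corpus


def _lexicon(**entries):
    return VariationLexicon(
        entries={k: tuple((s, CURATED) for s in v) for k, v in entries.items()}
    )


class TestTemplates:
    def test_parse_slots_and_literals(self):
        t = Template.from_text("t", "Patient is {Gender}")
        assert t.elements == (("lit", "Patient"), ("lit", "is"), ("slot", "Gender"))

    def test_template_without_slot_rejected(self):
        with pytest.raises(ValueError, match="slot"):
            Template.from_text("t", "no slots here")

    def test_default_templates_cover_all_core_types(self):
        from sdohminer.label_schema import default_schema

        covered = set()
        for t in default_training_templates():
            covered |= set(t.slot_types)
        assert covered == set(default_schema().core_types)


class TestGenerateSets:
    def test_single_variant_forced_output(self):
        t = Template.from_text("t", "Patient is {Gender}")
        sets = generate_synthetic_sets(
            [t], _lexicon(Gender=["female"]),
            AugmentationConfig(n_sets=1, split=(1, 0)),
        )
        sent = sets[0].sentences[0]
        assert sent.texts == ("Patient", "is", "female")
        assert sent.labels == ("O", "O", "B-Gender")

    def test_multi_token_variant_gets_inside_labels(self):
        t = Template.from_text("t", "Patient is {Gender}")
        sets = generate_synthetic_sets(
            [t], _lexicon(Gender=["non binary"]),
            AugmentationConfig(n_sets=1, split=(1, 0)),
        )
        assert sets[0].sentences[0].labels == ("O", "O", "B-Gender", "I-Gender")

    def test_default_config_emits_3000_sets_split_1500_1500(self):
        sets = generate_synthetic_sets(
            default_training_templates(),
            default_curated_lexicon(),
            AugmentationConfig(seed=3),
        )
        assert len(sets) == 3000
        assert sum(1 for s in sets if s.source == "full") == 1500
        assert sum(1 for s in sets if s.source == "curated") == 1500
        assert len({s.set_id for s in sets}) == 3000

    def test_each_set_is_one_instantiation_per_template(self):
        templates = default_training_templates()
        sets = generate_synthetic_sets(
            templates, default_curated_lexicon(),
            AugmentationConfig(n_sets=4, split=(2, 2)),
        )
        assert all(len(s.sentences) == len(templates) for s in sets)

    def test_generated_sentences_are_valid_bio(self):
        sets = generate_synthetic_sets(
            default_training_templates(), default_curated_lexicon(),
            AugmentationConfig(n_sets=20, split=(10, 10), seed=1),
        )
        c = make_corpus([])  # build a corpus to validate
        from sdohminer.corpus import Document, LabeledCorpus

        docs = tuple(
            Document(doc_id=f"s{i}", sentences=s.sentences)
            for i, s in enumerate(sets)
        )
        validate_bio(LabeledCorpus(docs))

    def test_seed_determinism(self):
        cfg = AugmentationConfig(n_sets=50, split=(25, 25), seed=9)
        a = generate_synthetic_sets(
            default_training_templates(), default_curated_lexicon(), cfg
        )
        b = generate_synthetic_sets(
            default_training_templates(), default_curated_lexicon(), cfg
        )
        assert [
            [s.texts for s in x.sentences] for x in a
        ] == [[s.texts for s in x.sentences] for x in b]

    def test_uncovered_slot_errors(self):
        t = Template.from_text("t", "Patient is {Gender}")
        with pytest.raises(KeyError, match="Gender"):
            generate_synthetic_sets(
                [t], _lexicon(Age=["62"]),
                AugmentationConfig(n_sets=1, split=(1, 0)),
            )

    def test_curated_only_sets_never_use_corpus_rare_variants(self):
        t = Template.from_text("t", "{Housing}")
        lex = VariationLexicon(
            entries={
                "Housing": (("curated house", CURATED), ("rare shelter", CORPUS_RARE))
            }
        )
        sets = generate_synthetic_sets(
            [t], lex, AugmentationConfig(n_sets=40, split=(20, 20), seed=2)
        )
        for s in sets[20:]:
            assert s.sentences[0].texts[0] == "curated"

    def test_variant_usage_counts_total(self):
        t = Template.from_text("t", "{Gender} and {Age}")
        sets = generate_synthetic_sets(
            [t], _lexicon(Gender=["female", "male"], Age=["62"]),
            AugmentationConfig(n_sets=30, split=(15, 15), seed=0),
        )
        usage = variant_usage(sets)
        assert sum(v for (t_, _), v in usage.items() if t_ == "Gender") == 30
        assert usage[("Age", "62")] == 30


class TestBuildLexicon:
    def test_empty_corpus_keeps_curated_only(self):
        from sdohminer.corpus import LabeledCorpus

        lex = build_variation_lexicon(
            LabeledCorpus(()), _lexicon(Gender=["female"])
        )
        assert lex.entries["Gender"] == (("female", CURATED),)

    def test_rare_span_extracted_with_source_tag(self):
        c = make_corpus(
            [[
                [("homeless", "B-Housing"), ("shelter", "I-Housing")],
                [("f", "B-Gender")] * 1,
            ]]
        )
        # Housing share 50% -> set threshold above it so Housing counts as rare
        lex = build_variation_lexicon(c, _lexicon(Gender=["x"]), rare_threshold=0.6)
        assert ("homeless shelter", CORPUS_RARE) in lex.entries["Housing"]

    def test_rare_type_set_matches_brute_force_tally(self, rng):
        c = random_bio_corpus(rng, n_docs=30, p_entity=0.4)
        threshold = 0.15
        lex = build_variation_lexicon(c, _lexicon(), rare_threshold=threshold)
        mentions = all_mentions(c)
        from collections import Counter

        tally = Counter(m.entity_type for m in mentions)
        total = sum(tally.values())
        expected_rare = {t for t, n in tally.items() if n / total < threshold}
        assert set(lex.entries) == expected_rare


class TestEmbedding:
    def test_zero_sets_identity(self, rng):
        c = random_bio_corpus(rng)
        out = embed_sets(c, [], seed=0)
        assert [(t.text, t.label) for t in out.iter_tokens()] == [
            (t.text, t.label) for t in c.iter_tokens()
        ]

    def test_single_set_recorded_on_host(self):
        c = make_corpus([[[("a", "O")]]])
        sets = generate_synthetic_sets(
            [Template.from_text("t", "{Age}")], _lexicon(Age=["62"]),
            AugmentationConfig(n_sets=1, split=(1, 0)),
        )
        out = embed_sets(c, sets, seed=0)
        d = out.documents[0]
        assert len(d.sentences) == 2
        assert d.provenance == "augmented"
        assert d.set_ids == (sets[0].set_id,)

    def test_empty_corpus_rejected(self):
        from sdohminer.corpus import LabeledCorpus

        with pytest.raises(ValueError):
            embed_sets(LabeledCorpus(()), [], seed=0)

    def test_conservation_and_determinism(self, rng):
        c = random_bio_corpus(rng, n_docs=12)
        sets = generate_synthetic_sets(
            default_training_templates(), default_curated_lexicon(),
            AugmentationConfig(n_sets=100, split=(50, 50), seed=4),
        )
        out1 = embed_sets(c, sets, seed=7)
        out2 = embed_sets(c, sets, seed=7)
        assert [(t.text, t.label) for t in out1.iter_tokens()] == [
            (t.text, t.label) for t in out2.iter_tokens()
        ]
        # token ledger balances
        assert out1.n_tokens == c.n_tokens + sum(s.n_tokens for s in sets)
        # original tokens survive in order within each document
        synth_texts = {
            (t.text, t.label) for s in sets for sent in s.sentences for t in sent
        }
        for orig_doc, new_doc in zip(c.documents, out1.documents):
            orig_sents = [s.labels + s.texts for s in orig_doc.sentences]
            new_sents = [s.labels + s.texts for s in new_doc.sentences]
            it = iter(new_sents)
            assert all(s in it for s in orig_sents)  # subsequence check

    def test_set_sentences_stay_contiguous(self, rng):
        c = make_corpus([[[("a", "O")], [("b", "O")]]])
        templates = [
            Template.from_text("t1", "{Age}"),
            Template.from_text("t2", "{Gender}"),
        ]
        sets = generate_synthetic_sets(
            templates, _lexicon(Age=["62"], Gender=["female"]),
            AugmentationConfig(n_sets=1, split=(1, 0)),
        )
        out = embed_sets(c, sets, seed=1)
        texts = [s.texts for s in out.documents[0].sentences]
        i = texts.index(("62",))
        assert texts[i + 1] == ("female",)


class TestGeneralizationTemplates:
    def test_higher_O_density_than_every_base(self):
        base = default_training_templates()
        derived = make_generalization_templates(base)
        max_base = max(t.o_proportion for t in base)
        assert all(t.o_proportion > max_base for t in derived)

    def test_slot_orders_disjoint_from_base(self):
        base = default_training_templates()
        derived = make_generalization_templates(base)
        base_orders = {t.slot_types for t in base}
        assert all(t.slot_types not in base_orders for t in derived)

    def test_some_template_lacks_gender(self):
        derived = make_generalization_templates(default_training_templates())
        assert any("Gender" not in t.slot_types for t in derived)
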