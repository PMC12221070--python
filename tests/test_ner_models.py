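"""Encoding alignment, backprop correctness, training behaviour."""

import numpy as np
import pytest

from sdohminer.corpus import Document, LabeledCorpus, Sentence, Token
from sdohminer.ner import (
    IGNORE_INDEX,
    TrainConfig,
    Vocab,
    decode,
    encode,
    encode_padded,
    evaluate,
    inverse_frequency_weights,
    split_documents,
    subword_pieces,
    train,
)
from sdohminer.ner.models import (
    BackendUnavailableError,
    MODEL_FAMILIES,
    RecurrentTagger,
    register_model_family,
)

from conftest import make_corpus


LABELS3 = ["O", "B-Age", "I-Age"]


def _segment(words_labels):
    return [Token(text=w, label=lab) for w, lab in words_labels]


class TestSubwordEncoding:
    def test_short_word_is_single_piece(self):
        assert subword_pieces("male") == ["male"]

    def test_long_word_splits_with_continuation_marks(self):
        pieces = subword_pieces("unemployment")
        assert pieces[0] == "unem"
        assert all(p.startswith("##") for p in pieces[1:])
        assert "".join([pieces[0]] + [p[2:] for p in pieces[1:]]) == "unemployment"

    def test_empty_segment_encodes_all_pad(self):
        vocab = Vocab([])
        (batch,) = encode([[]], vocab, LABELS3)
        assert batch.attention_mask.sum() == 0
        assert (batch.label_ids == IGNORE_INDEX).all()

    def test_mask_accounts_for_subwords_and_specials(self):
        seg = _segment([("hospitalization", "O"), ("62", "B-Age"), ("yr", "I-Age")])
        vocab = Vocab.from_segments([seg], subword=True)
        (batch,) = encode([seg], vocab, LABELS3)
        n_pieces = sum(len(subword_pieces(t.text)) for t in seg)
        assert batch.attention_mask.sum() == n_pieces + 2  # CLS + SEP
        assert len(batch.input_ids) == 512

    def test_round_trip_decode(self):
        seg = _segment(
            [("hospitalization", "O"), ("62", "B-Age"), ("years", "I-Age")]
        )
        vocab = Vocab.from_segments([seg], subword=True)
        batches = encode([seg], vocab, LABELS3)
        (words,) = decode(batches, vocab, LABELS3)
        assert words == [(t.text, t.label) for t in seg]

    def test_label_alignment_matches_brute_force_map(self, rng):
        words = ["w", "hospitalization", "rehabilitation", "62", "yr", "x" * 20]
        seg = []
        for _ in range(40):
            w = words[int(rng.integers(len(words)))]
            lab = LABELS3[int(rng.integers(3))]
            seg.append(Token(text=w, label=lab))
        vocab = Vocab.from_segments([seg], subword=True)
        (batch,) = encode([seg], vocab, LABELS3)
        # oracle: label sequence at first-subword positions, IGNORE elsewhere
        expected = [IGNORE_INDEX]  # CLS
        for t in seg:
            pieces = subword_pieces(t.text)
            expected.append(LABELS3.index(t.label))
            expected.extend([IGNORE_INDEX] * (len(pieces) - 1))
        expected.append(IGNORE_INDEX)  # SEP
        got = batch.label_ids[batch.attention_mask == 1].tolist()
        assert got == expected

    def test_overflowing_words_truncated_with_warning(self):
        seg = _segment([("w%d" % i, "O") for i in range(40)])
        vocab = Vocab.from_segments([seg])
        with pytest.warns(UserWarning, match="truncated"):
            (batch,) = encode([seg], vocab, LABELS3, max_len=16)
        assert batch.n_truncated_words == 40 - 14  # window minus CLS/SEP

    def test_padded_encoding_for_recurrent_models(self):
        seg = _segment([("a", "O"), ("b", "B-Age")])
        vocab = Vocab.from_segments([seg])
        (batch,) = encode_padded([seg], vocab, LABELS3, max_len=8)
        assert batch.attention_mask.tolist() == [1, 1, 0, 0, 0, 0, 0, 0]
        assert batch.label_ids[:2].tolist() == [0, 1]


class TestGradients:
    @pytest.mark.parametrize("family", ["rnn", "gru", "bilstm"])
    def test_analytic_gradients_match_finite_differences(self, family, rng):
        vocab = Vocab([f"w{i}" for i in range(8)])
        tagger = RecurrentTagger(
            family, vocab, LABELS3, embed_dim=3, hidden_size=4, dropout=0.0, seed=0
        )
        B, T = 2, 5
        ids = rng.integers(0, len(vocab), (B, T))
        mask = np.ones((B, T), dtype=np.int64)
        mask[1, 3:] = 0
        labs = rng.integers(0, 3, (B, T))
        labs[mask == 0] = -1
        tw = mask.astype(float)

        def loss_fn():
            probs, _ = tagger._forward(ids, mask, train=False)
            y = labs.T
            valid = y >= 0
            tt, bb = np.nonzero(valid)
            w = tw.T[tt, bb]
            return float(
                -(np.log(probs[tt, bb, y[tt, bb]] + 1e-12) * w).sum() / w.sum()
            )

        probs, cache = tagger._forward(ids, mask, train=False)
        grads, _ = tagger._backward(probs, labs, tw, cache)
        eps = 1e-6
        for name in sorted(grads):
            flat = tagger.params[name].reshape(-1)
            gflat = grads[name].reshape(-1)
            idxs = rng.choice(flat.size, size=min(5, flat.size), replace=False)
            for k in idxs:
                old = flat[k]
                flat[k] = old + eps
                lp = loss_fn()
                flat[k] = old - eps
                lm = loss_fn()
                flat[k] = old
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(gflat[k], abs=1e-5), name


class TestTraining:
    def _separable_corpus(self, n_docs=20, seed=0):
        """Two entity types with disjoint vocabularies — linearly separable."""
        rng = np.random.default_rng(seed)
        docs = []
        for di in range(n_docs):
            sents = []
            for _ in range(5):
                toks = []
                for _ in range(8):
                    r = rng.random()
                    if r < 0.2:
                        toks.append(Token(f"age{int(rng.integers(5))}", "B-Age"))
                    elif r < 0.4:
                        toks.append(Token(f"gen{int(rng.integers(5))}", "B-Gender"))
                    else:
                        toks.append(Token(f"o{int(rng.integers(10))}", "O"))
                sents.append(Sentence(tuple(toks)))
            docs.append(Document(doc_id=f"d{di}", sentences=tuple(sents)))
        return LabeledCorpus(tuple(docs))

    def test_loss_decreases_on_sanity_fixture(self):
        c = self._separable_corpus()
        labels = ["O", "B-Age", "I-Age", "B-Gender", "I-Gender"]
        tagger = train(c, labels, TrainConfig(model_family="rnn", epochs=6, seed=0))
        assert tagger.loss_history[-1] < tagger.loss_history[0]

    def test_separable_two_type_corpus_reaches_high_training_f1(self):
        c = self._separable_corpus()
        labels = ["O", "B-Age", "I-Age", "B-Gender", "I-Gender"]
        tagger = train(
            c, labels, TrainConfig(model_family="gru", epochs=10, seed=0)
        )
        rep = evaluate(tagger.predict_scores(c), c, labels)
        assert rep.macro_f1_excl_O >= 0.99

    def test_constant_O_corpus_predicts_O_and_warns_on_excl_metric(self):
        c = make_corpus([[[("a", "O"), ("b", "O")], [("c", "O")]]] * 3)
        labels = ["O", "B-Age", "I-Age"]
        tagger = train(c, labels, TrainConfig(model_family="rnn", epochs=3, seed=0))
        preds = tagger.predict_labels(c)
        assert set(preds) == {"O"}
        with pytest.warns(UserWarning):
            rep = evaluate(tagger.predict_scores(c), c, labels)
        assert np.isnan(rep.macro_f1_excl_O)

    def test_score_rows_on_probability_simplex(self):
        c = self._separable_corpus(n_docs=3)
        labels = ["O", "B-Age", "I-Age", "B-Gender", "I-Gender"]
        tagger = train(c, labels, TrainConfig(epochs=2, seed=0))
        scores = tagger.predict_scores(c)
        assert scores.shape == (c.n_tokens, len(labels))
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-9)

    def test_label_outside_schema_rejected_before_training(self):
        c = make_corpus([[[("a", "B-Mystery")]]])
        with pytest.raises(ValueError, match="Mystery"):
            train(c, LABELS3, TrainConfig(epochs=1))

    def test_inverse_frequency_weights_match_recount(self, rng):
        from conftest import random_bio_corpus
        from collections import Counter

        c = random_bio_corpus(rng, n_docs=10)
        labels = sorted(c.labels_used()) + ["B-Unseen"]
        w = inverse_frequency_weights(c, labels)
        counts = Counter(t.label for t in c.iter_tokens())
        inv = {lab: 1.0 / counts[lab] for lab in labels if counts.get(lab)}
        mean_inv = np.mean(list(inv.values()))
        for i, lab in enumerate(labels):
            if lab in inv:
                assert w[i] == pytest.approx(inv[lab] / mean_inv)
            else:
                assert w[i] == 1.0
        assert np.mean([w[i] for i, lab in enumerate(labels) if lab in inv]) == (
            pytest.approx(1.0)
        )

    def test_seed_determinism_of_training(self):
        c = self._separable_corpus(n_docs=5)
        labels = ["O", "B-Age", "I-Age", "B-Gender", "I-Gender"]
        cfg = TrainConfig(model_family="gru", epochs=3, seed=42)
        s1 = train(c, labels, cfg).predict_scores(c)
        s2 = train(c, labels, cfg).predict_scores(c)
        np.testing.assert_array_equal(s1, s2)

    def test_transformer_family_requires_registered_backend(self):
        c = self._separable_corpus(n_docs=2)
        labels = ["O", "B-Age", "I-Age", "B-Gender", "I-Gender"]
        with pytest.raises(BackendUnavailableError, match="register"):
            train(c, labels, TrainConfig(model_family="transformer_finetune"))

    def test_registered_backend_is_used(self):
        calls = []

        def factory(**kw):
            calls.append(kw)
            return MODEL_FAMILIES["rnn"](**kw)

        register_model_family("custom", factory)
        try:
            c = self._separable_corpus(n_docs=2)
            labels = ["O", "B-Age", "I-Age", "B-Gender", "I-Gender"]
            train(c, labels, TrainConfig(model_family="custom", epochs=1))
            assert calls
        finally:
            MODEL_FAMILIES.pop("custom", None)


class TestClassWeightingEfficacy:
    def _imbalanced_corpus(self, seed):
        """~100:1 majority:minority, with the minority surface form shared
        with 'O' so an unweighted fit collapses it into the background."""
        rng = np.random.default_rng(seed)
        docs = []
        for di in range(30):
            sents = []
            for _ in range(5):
                toks = []
                for _ in range(10):
                    r = rng.random()
                    if r < 0.30:
                        toks.append(Token(f"maj{int(rng.integers(5))}", "B-Majority"))
                    elif r < 0.303:
                        toks.append(Token("amb", "B-Minority"))
                    elif r < 0.31:
                        toks.append(Token("amb", "O"))
                    else:
                        toks.append(Token(f"o{int(rng.integers(10))}", "O"))
                sents.append(Sentence(tuple(toks)))
            docs.append(Document(doc_id=f"d{di}", sentences=tuple(sents)))
        return LabeledCorpus(tuple(docs))

    def test_weighting_improves_minority_f1_majority_of_seeds(self):
        labels = ["O", "B-Majority", "I-Majority", "B-Minority", "I-Minority"]
        wins = 0
        for seed in (0, 1, 2):
            c = self._imbalanced_corpus(seed)
            f1 = {}
            for weighting in ("inverse", "none"):
                tagger = train(
                    c,
                    labels,
                    TrainConfig(
                        model_family="rnn", epochs=8, seed=seed,
                        class_weighting=weighting, dropout=0.0,
                    ),
                )
                rep = evaluate(tagger.predict_scores(c), c, labels)
                f1[weighting] = rep.per_class_f1.get("B-Minority", 0.0)
            if f1["inverse"] > f1["none"]:
                wins += 1
        assert wins >= 2


def test_document_split_is_disjoint_and_seeded():
    docs = tuple(
        Document(doc_id=f"d{i}", sentences=(Sentence((Token("x"),)),))
        for i in range(10)
    )
    c = LabeledCorpus(docs)
    tr1, te1 = split_documents(c, 0.8, seed=3)
    tr2, te2 = split_documents(c, 0.8, seed=3)
    assert {d.doc_id for d in tr1.documents} == {d.doc_id for d in tr2.documents}
    assert len(tr1) == 8 and len(te1) == 2
    assert not ({d.doc_id for d in tr1.documents} & {d.doc_id for d in te1.documents})
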