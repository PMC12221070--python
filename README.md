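# sdohminer

Tools for mining **social determinants of health (SDOH)** from clinical
case-report text — built for equity-focused analyses of Post COVID-19
Condition (long COVID) literature, where attributes such as race, housing
status, insurance coverage and sexual orientation are sparsely and unevenly
documented.

The package implements a complete working pipeline around a BIO-labeled
corpus in CoNLL format:

1. **Corpus I/O** — read/write CoNLL (token, BIO label, optional per-token
   tagger confidence), repair dangling `I-` labels, and segment documents
   into ≤512-token windows without splitting sentences.
2. **Label schema** — a refined inventory of 26 core entity types plus `O`
   (27 classes; 53 labels after B-/I- expansion), a many-to-one refinement
   map from two upstream taggers' raw inventories, and a dual-tagger merge
   where a secondary tagger overrides designated types (default: `Age`,
   `Vaccine`).
3. **Filtration** — demote entity labels with confidence < 0.90 to `O`,
   demote numeric tokens labeled as anything but `Age`, and (for training
   subsets only) drop all-`O` sentences.
4. **Augmentation** — instantiate slotted sentence templates from an entity
   variation lexicon (corpus-rare mentions + curated variants), producing
   3,000 uniquely identified synthetic sentence sets per regime
   (1,500 full-lexicon + 1,500 curated-only) and embedding them at random
   positions in host documents. A generalization regime derives sparser
   templates with permuted slot orders.
5. **NER harness** — numpy-implemented RNN / GRU / BiLSTM token taggers
   (Adam, sparse cross-entropy, inverse-frequency class weighting,
   dropout), a pluggable slot for transformer fine-tuning backends, and
   evaluation: per-class F1, macro F1 including/excluding `O`, and macro
   one-vs-one / one-vs-rest ROC AUC.
6. **Entity analysis** — mention-level entity richness per document,
   frequency shares of non-`O` types, and ordered entity-type trigram
   tables over the top-k most frequent types.
7. **Rule-based NLI** — per-type statements (e.g. *"Has medical
   insurance"*) with entailment/contradiction lexicons, synonym expansion,
   word-boundary matching over mention surfaces, and aggregation in
   restricted (type-matched) vs. full modes.
8. **Synthetic corpus generator** — seeded case-report-like corpora with
   controllable `O` dominance, skewed type frequencies, span structure,
   confidences and label noise, so the whole pipeline is testable without
   any external data.

## The core quantities

For a tagger emitting per-token scores $p_i \in \Delta^{L-1}$ over the 53
BIO labels, evaluation uses token-level per-class F1
$F_1^{(c)} = 2\,\mathrm{TP}_c /(2\,\mathrm{TP}_c + \mathrm{FP}_c + \mathrm{FN}_c)$,
the unweighted macro average over classes present in the reference (with
and without the dominant `O` class), and multiclass ROC AUC: one-vs-rest
$\mathrm{AUC}_c$ per supported class, and one-vs-one
$\frac{1}{|P|}\sum_{(i,j)} \mathrm{AUC}(p_{\cdot i};\, y{=}i \mid y \in \{i,j\})$
over ordered pairs of supported classes, with mid-rank tie handling.

Distribution analyses operate on *mentions* (maximal `B-X (I-X)*` runs):
frequency shares are percentages of all non-`O` mentions; trigram tables
slide a width-3, stride-1 window over each document's mention-type
sequence. NLI percentages are per statement over applicable outcomes only:
%entailment + %contradiction = 100.

## Worked example

Run the full pipeline on a 50-document synthetic corpus (2% label noise,
70% `O` share), with a small subset layout and 60 synthetic sets:

```python
from sdohminer.pipeline import RunConfig, run_pipeline
from sdohminer.synthetic_corpus import CorpusSpec
from sdohminer.ner import TrainConfig

cfg = RunConfig(
    synth_spec=CorpusSpec(n_documents=50, noise_rate=0.02, o_share=0.7, seed=11),
    subset_sizes=(10, 25, 15), n_sets=60, set_split=(30, 30),
    train_cfg=TrainConfig(epochs=5, seed=1), seed=11,
)
res = run_pipeline(cfg)
for name, rep in res.artifacts["metrics"].items():
    print(name, round(rep.macro_f1_excl_O, 3), round(rep.macro_auc_ovr, 3))
print(res.artifacts["analysis"]["frequency_table"].head(5).round(2))
```

prints

```
optimization_test 0.847 0.997
generalization 0.743 0.979
Condition         34.56
Age               15.61
Access_To_Care     6.55
Treatment          6.08
Severity           5.75
```

The GRU tagger recovers the planted labels well on the optimization test
split (macro F1 excluding `O` of 0.85) and degrades on the generalization
set (0.74), whose synthetic sentences deliberately use different slot
orders and higher `O` density; the frequency table reflects the
condition-heavy skew the generator plants. The same stages are available
from the shell via the `miner` CLI (`miner synth`, `miner filter`,
`miner augment`, `miner train`, `miner analyze`, `miner nli`,
`miner run`).

## Layout

```
src/sdohminer/          corpus, corpus_io, label_schema, filtration,
                        augmentation, synthetic_corpus, entity_analysis,
                        nli_rules, pipeline, cli, ner/ (encoding, models,
                        train, metrics), data/ (YAML fixtures)
tests/                  pytest suite with brute-force oracles
docs/methods.md         models, assumptions, parameters, limitations
```
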