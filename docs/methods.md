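# Methods

This note documents the models, rules and numerical choices behind
`sdohminer`, in the order the pipeline applies them, together with the
assumptions each stage makes and what the synthetic test corpus does and
does not establish.

## Corpus model and CoNLL dialect

A corpus is documents → sentences → tokens; each token carries a surface
form, a BIO label (`O`, `B-Type`, `I-Type`) and optionally a tagger
confidence in [0, 1]. The CoNLL dialect is whitespace-delimited with the
token in column 1, the label in column 2 and an optional trailing numeric
confidence column; blank lines separate sentences and a configurable
`-DOCSTART-` marker separates documents. Upstream tagger output can
contain dangling `I-` labels; these are accepted on read and repaired to
`B-` by an explicit `repair_bio` pass rather than silently, so repair
counts are auditable. Raw text is tokenized by a deterministic
whitespace-plus-punctuation rule; subword tokenization is confined to the
encoding layer of the NER harness.

Segmentation packs whole sentences greedily, in document order, into
windows of at most 512 word tokens; a sentence longer than the window is
an error unless hard splitting is requested. The 512 limit is counted in
word tokens at this stage; the subword encoder re-checks its own window
after expansion and truncates with a warning, reporting the count.

## Label schema and refinement

The refined schema has 26 core entity types plus `O` — 27 classes, 53
labels after B-/I- expansion (`O` first, then B-/I- pairs in canonical
type order). The shipped refinement map collapses interrelated source
types (several disease labels → `Condition`; alcohol/smoking/substance-use
→ `Substance`; admission-discharge → `Access_To_Care`; food insecurity →
`Diet`; social exclusion → `Social_Support`; financial status → `Income`)
and demotes out-of-scope source types to `O`. It is a plain YAML file so a
different mapping can be dropped in without code changes. Type names are
normalized by replacing spaces with underscores; comparisons are
case-sensitive after normalization.

The dual-tagger merge is additive: the secondary tagger's label (and
confidence) replaces the primary's only where the secondary assigns a
non-`O` label of an override type (default `Age` and `Vaccine`, where a
clinical-trials tagger is the more reliable source); a secondary `O` never
erases a primary label.

## Filtration

Three rules, applied in fixed order (confidence floor → refinement →
numeric demotion → sentence drop):

- **Confidence floor** (default 0.90): entity tokens with confidence
  strictly below the floor become `O`. "Below" is read literally — a token
  at exactly 0.90 survives. Tokens without a confidence (human-reviewed
  labels) are exempt.
- **Numeric demotion**: a token whose text is numeric (digits, optionally
  with thousands separators, one decimal point, or a leading sign;
  word-numerals excluded) and whose label is neither `B-Age`/`I-Age` nor
  `O` becomes `O`. Dates, doses and lab values are the dominant numeric
  noise source; age is the one numeric entity retained.
- **All-`O` sentence removal**: applied to training subsets only, since it
  changes the class prior; evaluation subsets keep their natural `O`
  dominance. Documents emptied entirely are kept as empty shells so corpus
  accounting stays stable (a flag prunes them).

All three are idempotent, and the floor is monotone: raising it never
decreases the number of `O` tokens. Both properties are tested.

## Augmentation

A synthetic sentence *set* is one instantiation of each of the three
training templates (configurable down to one sentence per set). Slots are
filled by variants drawn uniformly from the entity-variation lexicon,
which unions curated per-type variants with corpus surface forms of rare
types — those whose share of all non-`O` mentions falls below a threshold
(default 1%, exposed as configuration since the rarity criterion is a
modelling choice). The default configuration emits 3,000 sets: the first
1,500 sample from the full lexicon, the remaining 1,500 from curated
entries alone. Each set carries a unique identifier and is embedded,
contiguous and in order, at a uniformly random sentence position of a
uniformly random host document; original tokens are never mutated or
reordered, so the token ledger balances exactly. Sampling is uniform
without per-variant balancing, but a usage report is emitted so sampling
skew is auditable.

Generalization-regime templates are derived programmatically from the
training templates with three guarantees: strictly higher literal-`O`
proportion than every training template, slot orders differing from every
training order, and the `Gender` slot absent from at least one template
(gender is already frequent pre-augmentation). This probes whether a
tagger has overfit the training sentence structures.

The shipped templates and curated lexicons are small illustrative
fixtures; larger externally generated dictionaries can replace them via
the same YAML layout.

## Synthetic corpus generator

The generator emulates the statistical structure of automatically tagged
case-report text: heavy `O` dominance (default share 0.85), strongly
skewed type frequencies (condition-like mentions at ~37% of non-`O`
tokens; race/sexual-orientation well below 1%), spans of 1–4 tokens,
per-token confidences, and independent per-token label noise (an `O`
token gains a random entity label; an entity token collapses to `O`).
Because spans are multi-token, entity types are sampled with probability
proportional to `share / E[span length]`, so *token*-level shares converge
to the requested frequencies; mention counts are exactly multinomial in
the corrected weights, which is what the goodness-of-fit test checks.
Confidences for correct labels are drawn as `1 − Beta(1, 12)`
(median ≈ 0.95, mostly above the 0.9 floor) and for corrupted labels as
`Uniform(0.2, 0.9)`, so the confidence-floor rule preferentially removes
planted noise the way it would remove low-confidence tagger errors. Ages
are digit strings so the numeric-demotion rule is exercised. The
pre-noise truth corpus is returned alongside the observed one for
recovery tests.

The generator makes no attempt at linguistic realism: surfaces come from
small closed vocabularies, sentences have no grammar, and document
structure is uniform. Passing tests therefore establish that the pipeline
machinery is correct under the modelled statistics — not that any tagger
reaches a particular accuracy on real clinical prose.

## NER harness

Encoding: transformer-style batches wrap each segment in start/separator
markers, expand words deterministically into fixed-width subword pieces,
pad to the 512 window, and align labels so only the first piece of each
word carries the label; continuations and specials are ignored in the
loss. Recurrent families consume plain padded word-id sequences.

The three recurrent families (simple RNN, GRU, bidirectional LSTM) are
implemented directly on numpy with manual backpropagation through time —
gradients are verified against central finite differences in the test
suite. Training uses Adam on a sparse cross-entropy loss with per-token
weights `class_weight[label] × sample_weight`; class weights default to
inverse label frequency normalized to mean 1 over the labels present,
which is the imbalance mitigation the schema's extreme skew requires.
Inverted dropout (default 0.1) is applied to the recurrent states.

Defaults are desk-scale: 15 epochs, learning rate 1e-2, embedding 24,
hidden 32, batch 32. From-scratch training of these small models under
Adam needs a step size of this order; the published full-scale regimes
(300 epochs at 1e-5 for transformer fine-tuning, 10 epochs at 1e-9 for
recurrent baselines) ship as named presets rather than defaults. No
transformer backend ships with the package; `transformer_finetune` is a
registry slot, and any object exposing per-token probability rows over the
53 labels plugs into training and evaluation.

F1 is token-level per BIO label (B- and I- sub-labels scored separately);
an exact-span micro-F1 report is available separately. Macro averages are
unweighted over classes present in the reference; absent classes are
skipped and listed. One-vs-one AUC averages, over ordered pairs of
supported classes (i, j), the AUC of the class-i score restricted to
samples of the two classes; one-vs-rest averages the per-class AUC.
Ties use mid-ranks. `macro_f1_excl_O` drops only the `O` *class* from the
average — `O` tokens still count as negatives for entity classes — and is
NaN (with a warning) when the reference contains no entity class.

The 80/20 split is document-level, unstratified, and seeded.

## Entity analyses

All distribution analyses count mentions (maximal `B-X (I-X)*` runs;
mentions do not span sentence boundaries). Richness is the number of
distinct non-`O` types per document. Frequency shares are percentages of
all non-`O` mentions, summing to 100. Trigram tables slide a width-3,
stride-1 window over each document's mention-type sequence — across
sentence boundaries by default, because the document (case-report
section) is the analysis unit; a flag restricts windows to sentences.
The top-k restriction (default 25) removes non-top-k mentions from the
sequence *before* windowing, so a window may span a dropped mention; a
break-at-dropped mode is available. Both modes are deterministic; the
default was chosen so the trigram table reflects the narrative order of
the frequent types rather than fragmenting at every rare mention.

## Rule-based NLI

Each entity type carries one statement. For binary attributes the
statement expresses presence/absence (social support, substance use,
marital status, disability, housing, insurance, violence/abuse,
employment, vaccination, mental health, access to care); for graded
attributes it encodes a meaningful binary break: education at/above high
school, white/Caucasian vs. not, English vs. not for language and
geography, senior adult, female-identifying, heterosexual,
terminal/rare/chronic condition, highly invasive treatment, highly severe
symptoms.

Matching operates on the mention surface (the extracted entity is the
string under assessment), case-insensitively, with word boundaries at both
phrase ends and internal whitespace normalized. Lexicons are expanded
through a synonym mapping (a small YAML resource ships; any mapping
plugs in), normalized and deduplicated; a term landing in both lists
after expansion is an error that forces manual curation. When both lists
match, the longest matched term wins; an exact length tie resolves to
Contradiction — the conservative choice, avoiding overstating positive
representation — and ties are rare under curated lexicons. Aggregation
reports percentages over applicable outcomes only (NotApplicable is
noise-prone and excluded); restricted mode scans only type-matched
mentions, full mode all mentions, so restricted applicable counts can
never exceed full-mode counts.

## Pipeline and reproducibility

Stages run in fixed order; each run is stamped with a config hash and the
seeds used, and per-stage counters (tokens demoted, sentences dropped,
sets embedded, truncations) make reruns auditable. Deterministic stages
reproduce byte-identical artifacts under an identical configuration. The
default subset layout (99 human-reviewed / 402 augmented-training / 208
generalization documents, 80/20 split) mirrors the study design the
pipeline supports and is fully overridable.

## Problem sizes used in verification

The test suite exercises the pipeline at deliberately small scale: the
tagger-recovery check trains a GRU on a ~9,000-token, 6-type synthetic
corpus with 2% label noise (three seeds); metric implementations are
checked against brute-force oracles on 100 random instances of up to
1,000 tokens and 7 classes; distribution and NLI properties are checked
on dozens of small random corpora; and the end-to-end run uses 50
documents with 60 synthetic sets. These sizes were chosen so the full
suite gives quick feedback while every property is still exercised at
non-trivial scale.

## Known limitations

- Generated text is statistically, not linguistically, case-report-like;
  no conclusion about accuracy on real clinical prose follows from the
  synthetic benchmarks.
- No transformer backend ships; full-scale fine-tuning requires
  registering an external backend satisfying the score-matrix contract.
- The shipped NLI lexicons and variation dictionaries are illustrative
  fixtures; production use should substitute curated, reviewed sets.
- The rarity threshold for lexicon building, the dual-match tie-break and
  the trigram drop mode are explicit configuration; results can be
  sensitive to them and reports should state the values used.
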