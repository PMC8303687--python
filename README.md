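# flavorlex

Mining flavor-descriptor lexicons from free-text product reviews.

## The problem

Sensory scientists build *descriptive lexicons* — curated vocabularies of
terms like "peaty", "vanilla", or "briny" that characterize the flavor of a
product category. Building one by Descriptive Analysis panel takes weeks of
trained-panel work, yet thousands of whisky (and wine, coffee, beer, ...)
reviews already contain these descriptors interspersed with ordinary
language. `flavorlex` implements a pipeline that learns to separate the two:

1. **Candidate generation** — reviews are tokenized, POS-tagged, and
   lemmatized; nouns, adjectives, and a configurable whitelist of verbs form
   the candidate-descriptor frequency table.
2. **Annotation** — candidates are paged to human annotators in
   frequency-priority batches (≤ 50 per page); a lemma is a descriptor iff
   at least **two of three** annotators say so, and the lemma's label is
   projected onto every surface token type it produces ("fruit" → "fruity",
   "fruits").
3. **Classification** — every *occurrence* of a labeled token type, located
   by (review, sentence, position), becomes a training instance. The input
   is the word's embedding plus the embeddings of the *n* = 3 words before
   and after it in the sentence (zero-vector `PAD` where the window crosses
   a sentence edge). A **dual-branch uni-directional LSTM** scores each
   occurrence as descriptor / non-descriptor.
4. **Lexicon extraction** — a trained model scores every word of a review;
   token types above a probability threshold form that whisky's lexicon.

## The model

Both inputs are embedded token sequences of dimension *d*:

```
context (2n × d) ──► LSTM(256) ──► Dense(128, relu) ─┐
                                                     ├─ concat ─► Dense(64) ─► Dense(32) ─► softmax(2)
word    (1 × d)  ──► LSTM(256) ──► Dense(128, relu) ─┘
```

Training minimizes binary cross entropy (softmax over one-hot two-class
targets) with Adam at learning rate 1e-4, batch size 32, for 3 epochs, with
20% of the training data held out for per-epoch validation. The stopping
epoch is chosen where validation loss starts rising while training loss
still falls (`detect_divergence_epoch`). The network — LSTM forward and
backward passes, dense layers, and the Adam update — is implemented in
numpy inside the package (`flavorlex.nn`) and is bit-reproducible for a
fixed seed.

Because annotated review corpora of this kind are not public, the package
ships a first-class **synthetic generator** (`flavorlex.synthetic`): word
types with known labels, embedding clusters at controllable separation *s*
(in units of within-cluster σ), controllable descriptor density, optional
context-dependent "ambiguous" words that are descriptive only after a cue
phrase ("notes of …"), and professional/hobbyist style pairs. Every stage
of the pipeline is tested end-to-end against these exact gold labels.

## Worked example

```python
from dataclasses import replace
from flavorlex import (SynthConfig, ModelConfig, run_experiment,
                       extract_lexicon, generate_embedding_space,
                       generate_corpus)
from flavorlex.synthetic import build_vocabulary, make_tagger

config = SynthConfig(n_reviews=300, separation=4.0, embedding_dim=50, seed=11)
vocab = build_vocabulary(config)
store, _ = generate_embedding_space(config, vocab)
reviews, gold = generate_corpus(replace(config, seed=12), vocab)

report = run_experiment(reviews, gold, store, tagger=make_tagger(vocab),
                        model_config=ModelConfig(seed=1), split_seed=13)
print(report.summary())
```

prints

```
Experiment report
============================================================
instances: 8651  (train 6921, test 1730)
class ratio (descriptor): 0.439
OOV rate: 0.0000   train/test type overlap: 0.947
------------------------------------------------------------
               accuracy  precision   recall       f1
LSTM            0.98960    0.98745  0.98994  0.98869
POS baseline    0.80867    0.70604  1.00000  0.82769
------------------------------------------------------------
recommended epochs (val-loss divergence): 3
```

8,651 word occurrences (43.9% descriptors) were split 80/20 at the
instance level; after three epochs the classifier scores 99.0% held-out
accuracy against 80.9% for the every-noun-and-adjective baseline (whose
recall is 1.0 by construction — descriptors *are* nouns and adjectives —
but whose precision is capped by all the non-descriptive nouns in running
text). `type overlap: 0.947` is the fraction of test occurrences whose word
type also appears in training — the known optimistic bias of instance-level
splitting; `split_examples(..., level="type")` offers the stricter
alternative. Extracting a lexicon from one review:

```python
lexicon = extract_lexicon(report.results, store, reviews[0],
                          tagger=make_tagger(vocab), threshold=0.5)
# [('desc0307', 1.0), ('desc0128', 1.0), ('desc0089', 1.0), ...]
```

The same workflow is available from the shell via the `flavorlex` command
(`simulate`, `prepare`, `queue`, `merge`, `build`, `train`, `curve`,
`eval`, `lexicon`, `viz`); every run writes a reproducibility manifest with
its config hash, seed, and input checksums.

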