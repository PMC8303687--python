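"""Synthetic review corpora and embedding spaces with known gold labels.

The generator emulates the statistical structure the descriptor-extraction
pipeline assumes, so every stage can be exercised end-to-end with exact gold
labels and no downloads or human annotation:

* a vocabulary of descriptor word types (tagged NOUN/ADJ), non-descriptor
  filler types (mixed POS), and closed-class function words;
* an embedding space where descriptor and non-descriptor types form two
  Gaussian clusters whose means lie ``separation`` within-cluster standard
  deviations apart (``separation=0`` collapses them into one cloud);
* review texts assembled from function words and descriptor insertions at a
  controllable density, with a trailing period per sentence;
* optional *ambiguous* types whose embedding sits between the clusters and
  whose gold label is 1 only when the occurrence is immediately preceded by
  a cue phrase ("notes of ..."), so their label is decidable only from
  context — mimicking words like "maple" that are descriptive in "a sweet
  maple aftertaste" but not in a distillery name;
* a writing-style pair: two corpora sharing the descriptor vocabulary but
  with disjoint cue-phrase inventories and different sentence lengths.

Defaults mirror the annotated-corpus conditions the pipeline targets:
499 descriptor / 1295 non-descriptor types and a descriptor density of 0.44,
giving the 44% / 56% positive/negative instance mix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .corpus import Review, RuleBasedTagger
from .embeddings import EmbeddingStore
from .exceptions import ValidationError

__all__ = [
    "SynthConfig",
    "Vocabulary",
    "StylePair",
    "build_vocabulary",
    "generate_embedding_space",
    "generate_corpus",
    "generate_style_pair",
    "make_tagger",
    "expected_pos_baseline_accuracy",
]

#: Closed-class function words and their POS tags (all non-descriptors).
FUNCTION_WORDS: dict[str, str] = {
    "the": "DET", "a": "DET", "an": "DET", "this": "DET", "that": "DET",
    "of": "ADP", "with": "ADP", "on": "ADP", "in": "ADP", "to": "ADP",
    "and": "CCONJ", "but": "CCONJ", "or": "CCONJ",
    "is": "AUX", "was": "AUX", "has": "AUX",
    "it": "PRON", "there": "PRON",
    "very": "ADV", "quite": "ADV",
}

#: Probability that a non-descriptor slot draws a function word (vs filler).
FUNCTION_CHOICE_P = 0.5

#: Probability that an ambiguous-type insertion is preceded by a cue phrase.
CUE_INSERTION_P = 0.5

_DEFAULT_CUES_B = ("brings to mind", "tastes like")


@dataclass
class SynthConfig:
    """Generator parameters; defaults are the study conditions."""

    n_descriptor_types: int = 499
    n_nondescriptor_types: int = 1295
    embedding_dim: int = 50
    separation: float = 4.0
    n_reviews: int = 2000
    sentences_per_review: tuple[int, int] = (3, 6)
    sentence_length: tuple[int, int] = (4, 9)
    descriptor_density: float = 0.44
    ambiguous_fraction: float = 0.0
    cue_phrases: tuple[str, ...] = ("notes of", "hints of")
    style: str = "professional"
    seed: int = 0

    def __post_init__(self) -> None:
        self.cue_phrases = tuple(self.cue_phrases)
        if self.n_descriptor_types < 1 or self.n_nondescriptor_types < 1:
            raise ValidationError("type counts must be >= 1")
        if not 0 <= self.descriptor_density <= 1:
            raise ValidationError(
                f"descriptor_density must be in [0,1], got {self.descriptor_density}")
        if not 0 <= self.ambiguous_fraction <= 1:
            raise ValidationError(
                f"ambiguous_fraction must be in [0,1], got {self.ambiguous_fraction}")
        if self.separation < 0:
            raise ValidationError(f"separation must be >= 0, got {self.separation}")
        for name in ("sentences_per_review", "sentence_length"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValidationError(f"{name} range invalid: ({lo}, {hi})")


@dataclass
class Vocabulary:
    """The word types of a synthetic world, with their POS tags."""

    descriptor_types: list[str]
    ambiguous_types: list[str]          # subset of descriptor_types
    filler_types: list[str]
    function_words: list[str]
    cue_phrases: tuple[str, ...]
    pos: dict[str, str]                 # every word type -> POS tag

    @property
    def all_types(self) -> list[str]:
        cue_words = [w for p in self.cue_phrases for w in p.split()]
        seen: list[str] = []
        for w in (self.descriptor_types + self.filler_types
                  + self.function_words + cue_words):
            if w not in seen:
                seen.append(w)
        return seen


def build_vocabulary(config: SynthConfig,
                     extra_cue_phrases: tuple[str, ...] = ()) -> Vocabulary:
    """Deterministic vocabulary for a config (no randomness involved).

    Descriptor types alternate NOUN/ADJ tags; the first
    ``round(ambiguous_fraction * n)`` of them are the ambiguous types.
    Filler (non-descriptor content) types are 70% NOUN/ADJ — the baseline's
    false positives — and 30% VERB/ADV; cue-phrase content words are tagged
    NOUN, cue function words keep their closed-class tags.
    """
    n_amb = round(config.ambiguous_fraction * config.n_descriptor_types)
    ambiguous = [f"ambig{i:04d}" for i in range(n_amb)]
    plain = [f"desc{i:04d}" for i in range(config.n_descriptor_types - n_amb)]
    descriptors = ambiguous + plain
    fillers = [f"plain{i:04d}" for i in range(config.n_nondescriptor_types)]

    pos: dict[str, str] = dict(FUNCTION_WORDS)
    for i, w in enumerate(descriptors):
        pos[w] = "NOUN" if i % 2 == 0 else "ADJ"
    for i, w in enumerate(fillers):
        r = i % 10
        if r < 7:
            pos[w] = "NOUN" if r % 2 == 0 else "ADJ"
        else:
            pos[w] = "VERB" if r < 9 else "ADV"
    cue_phrases = tuple(config.cue_phrases) + tuple(extra_cue_phrases)
    for phrase in cue_phrases:
        for w in phrase.split():
            pos.setdefault(w, "NOUN")
    return Vocabulary(descriptors, ambiguous, fillers,
                      list(FUNCTION_WORDS), cue_phrases, pos)


def make_tagger(vocab: Vocabulary) -> RuleBasedTagger:
    """A rule-based tagger that is exact on this vocabulary's corpora."""
    return RuleBasedTagger(vocab.pos)


def generate_embedding_space(
    config: SynthConfig, vocab: Vocabulary | None = None,
) -> tuple[EmbeddingStore, dict[str, int]]:
    """Draw the two-cluster embedding space; returns (store, type labels).

    Descriptor-type vectors are sampled around +mu and non-descriptor
    vectors (fillers, function words, cue words) around -mu, with unit
    within-cluster standard deviation and ``|2 mu| = separation``. Ambiguous
    types sit around the origin, equidistant from both clusters, so their
    vector alone carries no label information; in the returned type-label
    map they count as descriptors (their cued sense).
    """
    vocab = vocab or build_vocabulary(config)
    rng = np.random.default_rng(config.seed)
    d = config.embedding_dim
    direction = rng.standard_normal(d)
    direction /= np.linalg.norm(direction)
    mu = (config.separation / 2.0) * direction

    table: dict[str, np.ndarray] = {}
    labels: dict[str, int] = {}
    ambiguous = set(vocab.ambiguous_types)
    for w in vocab.descriptor_types:
        center = np.zeros(d) if w in ambiguous else mu
        table[w] = center + rng.standard_normal(d)
        labels[w] = 1
    nondesc = list(vocab.filler_types) + vocab.function_words
    for phrase in vocab.cue_phrases:
        for w in phrase.split():
            if w not in table and w not in nondesc:
                nondesc.append(w)
    for w in nondesc:
        if w in table:
            continue
        table[w] = -mu + rng.standard_normal(d)
        labels[w] = 0
    return EmbeddingStore(table), labels


def generate_corpus(
    config: SynthConfig, vocab: Vocabulary | None = None,
) -> tuple[list[Review], dict[tuple[str, int, int], int]]:
    """Assemble labeled review texts; returns (reviews, gold labels).

    Gold labels are positional: (review_id, sentence_index,
    filtered_position) -> 0/1 for every non-punctuation token. Each content
    slot is a descriptor insertion with probability ``descriptor_density``,
    otherwise a function word or filler. Ambiguous-type insertions are
    preceded by a cue phrase with probability 1/2 and are gold-positive only
    when cued; cue-phrase tokens themselves are gold-negative.
    """
    vocab = vocab or build_vocabulary(config)
    rng = np.random.default_rng(config.seed)
    ambiguous = set(vocab.ambiguous_types)
    reviews: list[Review] = []
    gold: dict[tuple[str, int, int], int] = {}
    lo_s, hi_s = config.sentences_per_review
    lo_w, hi_w = config.sentence_length
    n_desc = len(vocab.descriptor_types)
    n_fill = len(vocab.filler_types)
    n_func = len(vocab.function_words)

    for r in range(config.n_reviews):
        rid = f"r{r:05d}"
        sentences: list[str] = []
        for s_idx in range(int(rng.integers(lo_s, hi_s + 1))):
            words: list[str] = []
            labels: list[int] = []
            for _ in range(int(rng.integers(lo_w, hi_w + 1))):
                if rng.random() < config.descriptor_density:
                    w = vocab.descriptor_types[int(rng.integers(n_desc))]
                    if w in ambiguous:
                        cued = rng.random() < CUE_INSERTION_P
                        if cued:
                            for cw in vocab.cue_phrases[
                                    int(rng.integers(len(vocab.cue_phrases)))].split():
                                words.append(cw)
                                labels.append(0)
                        words.append(w)
                        labels.append(1 if cued else 0)
                    else:
                        words.append(w)
                        labels.append(1)
                else:
                    if rng.random() < FUNCTION_CHOICE_P:
                        words.append(vocab.function_words[int(rng.integers(n_func))])
                    else:
                        words.append(vocab.filler_types[int(rng.integers(n_fill))])
                    labels.append(0)
            for pos_idx, label in enumerate(labels):
                gold[(rid, s_idx, pos_idx)] = label
            sentences.append(" ".join(words) + ".")
        reviews.append(Review(review_id=rid, text=" ".join(sentences),
                              source=config.style, reviewer="synthetic"))
    return reviews, gold


@dataclass
class StylePair:
    """Two corpora sharing a descriptor vocabulary but differing in style."""

    store: EmbeddingStore
    type_labels: dict[str, int]
    vocab: Vocabulary
    reviews_a: list[Review] = field(default_factory=list)
    gold_a: dict = field(default_factory=dict)
    reviews_b: list[Review] = field(default_factory=list)
    gold_b: dict = field(default_factory=dict)
    config_a: SynthConfig | None = None
    config_b: SynthConfig | None = None


def generate_style_pair(
    config: SynthConfig,
    cue_phrases_b: tuple[str, ...] = _DEFAULT_CUES_B,
    sentence_length_b: tuple[int, int] = (8, 15),
) -> StylePair:
    """Generate a "professional" / "hobbyist" corpus pair.

    Corpus A uses ``config`` as-is; corpus B shares the descriptor and
    filler vocabulary but has a disjoint cue-phrase inventory, a longer
    sentence-length range, and an independent seed. The embedding store
    covers both cue inventories so either corpus can be embedded.
    """
    overlap = {w for p in config.cue_phrases for w in p.split()} & \
              {w for p in cue_phrases_b for w in p.split()}
    overlap -= set(FUNCTION_WORDS)
    if overlap:
        raise ValidationError(
            f"cue inventories must be disjoint on content words: {sorted(overlap)}")
    vocab_union = build_vocabulary(config, extra_cue_phrases=cue_phrases_b)
    store, type_labels = generate_embedding_space(config, vocab_union)
    vocab_a = replace_cues(vocab_union, config.cue_phrases)
    vocab_b = replace_cues(vocab_union, cue_phrases_b)
    config_b = replace(config, cue_phrases=cue_phrases_b,
                       sentence_length=sentence_length_b,
                       style="hobbyist", seed=config.seed + 1)
    reviews_a, gold_a = generate_corpus(config, vocab_a)
    reviews_b, gold_b = generate_corpus(config_b, vocab_b)
    return StylePair(store, type_labels, vocab_union, reviews_a, gold_a,
                     reviews_b, gold_b, config, config_b)


def replace_cues(vocab: Vocabulary, cue_phrases: tuple[str, ...]) -> Vocabulary:
    """A view of ``vocab`` restricted to one cue-phrase inventory."""
    return Vocabulary(vocab.descriptor_types, vocab.ambiguous_types,
                      vocab.filler_types, vocab.function_words,
                      tuple(cue_phrases), vocab.pos)


def expected_pos_baseline_accuracy(config: SynthConfig,
                                   vocab: Vocabulary | None = None) -> float:
    """Analytic accuracy of the NOUN/ADJ-baseline on this generator.

    Derived from the slot model: descriptor tokens are always NOUN/ADJ (the
    baseline gets non-ambiguous ones right, uncued ambiguous ones wrong);
    non-descriptor slots split between function words (never NOUN/ADJ,
    correct) and fillers (correct only for the non-NOUN/ADJ share); cue
    tokens are correct when their POS is closed-class.
    """
    vocab = vocab or build_vocabulary(config)
    dd = config.descriptor_density
    af = config.ambiguous_fraction if vocab.ambiguous_types else 0.0
    filler_na = np.mean([vocab.pos[w] in ("NOUN", "ADJ") for w in vocab.filler_types])
    cue_words = [w for p in vocab.cue_phrases for w in p.split()]
    cue_len = np.mean([len(p.split()) for p in vocab.cue_phrases])
    cue_correct = np.mean([vocab.pos[w] not in ("NOUN", "ADJ") for w in cue_words]) \
        if cue_words else 0.0

    correct = (
        dd * (1 - af)                                  # plain descriptors
        + dd * af * CUE_INSERTION_P                    # cued ambiguous (label 1)
        + dd * af * CUE_INSERTION_P * cue_len * cue_correct
        + (1 - dd) * (FUNCTION_CHOICE_P
                      + (1 - FUNCTION_CHOICE_P) * (1 - filler_na))
    )
    total = 1 + dd * af * CUE_INSERTION_P * cue_len
    return float(correct / total)
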