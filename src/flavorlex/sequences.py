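"""Token-instance indexing, context-window extraction, and example assembly.

Classification happens per *instance*: one occurrence of a labeled token
type, addressed by (review, sentence, position-in-sentence). Positions are
counted over the punctuation-stripped, stop-word-retaining token sequence,
and the n-before/n-after context window never crosses a sentence boundary —
missing context is filled with PAD, which embeds as the zero vector.
"""

from __future__ import annotations

import csv
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .annotation import LabeledTokenType
from .corpus import TaggedToken
from .embeddings import PAD, EmbeddingStore
from .exceptions import SchemaError, ValidationError

__all__ = [
    "TokenInstance",
    "SequenceExample",
    "sentence_words",
    "index_instances",
    "instances_from_gold",
    "extract_context",
    "assemble_examples",
    "examples_to_arrays",
    "split_examples",
    "type_overlap_fraction",
    "class_ratio",
    "write_instance_table",
    "read_instance_table",
]


@dataclass(frozen=True)
class TokenInstance:
    """One occurrence of a labeled token type at a unique corpus address."""

    token_type: str
    review_id: str
    sentence_index: int
    filtered_position: int
    label: int
    pos: str | None = None


@dataclass(frozen=True)
class SequenceExample:
    """Model-ready example: 2n context vectors, the word vector, its label."""

    context_vectors: np.ndarray  # (2n, d): n before then n after, reading order
    word_vector: np.ndarray      # (d,)
    label: int
    provenance: TokenInstance


def sentence_words(tokens: Iterable[TaggedToken]) -> dict[int, list[TaggedToken]]:
    """Group a review's tokens by sentence, punctuation dropped.

    Within each sentence the tokens are ordered by ``filtered_position``, so
    list index == filtered position.
    """
    sentences: dict[int, list[TaggedToken]] = {}
    for tok in tokens:
        if tok.is_punct:
            continue
        sentences.setdefault(tok.sentence_index, []).append(tok)
    for sent in sentences.values():
        sent.sort(key=lambda t: t.filtered_position)  # type: ignore[arg-type]
    return sentences


def index_instances(
    tokens_by_review: Mapping[str, list[TaggedToken]],
    labeled_types: Mapping[str, LabeledTokenType],
) -> list[TokenInstance]:
    """Locate every occurrence of each labeled token type.

    Returns one :class:`TokenInstance` per occurrence, labels inherited from
    the token type, in deterministic (review, sentence, position) order.
    """
    instances: list[TokenInstance] = []
    for review_id in sorted(tokens_by_review):
        for sent_idx, sent in sorted(sentence_words(tokens_by_review[review_id]).items()):
            for tok in sent:
                ltype = labeled_types.get(tok.surface.lower())
                if ltype is None:
                    continue
                instances.append(TokenInstance(
                    ltype.token_type, review_id, sent_idx,
                    tok.filtered_position, ltype.label, tok.pos))  # type: ignore[arg-type]
    return instances


def instances_from_gold(
    tokens_by_review: Mapping[str, list[TaggedToken]],
    gold: Mapping[tuple[str, int, int], int],
) -> list[TokenInstance]:
    """Build instances from positional gold labels (synthetic corpora).

    ``gold`` maps (review_id, sentence_index, filtered_position) to a 0/1
    label; unlike lemma-level annotation this allows the same word type to
    carry different labels at different positions (context-dependent words).
    """
    instances: list[TokenInstance] = []
    for review_id in sorted(tokens_by_review):
        for sent_idx, sent in sorted(sentence_words(tokens_by_review[review_id]).items()):
            for tok in sent:
                label = gold.get((review_id, sent_idx, tok.filtered_position))
                if label is None:
                    continue
                instances.append(TokenInstance(
                    tok.surface.lower(), review_id, sent_idx,
                    tok.filtered_position, int(label), tok.pos))  # type: ignore[arg-type]
    return instances


def extract_context(sentence: list, position: int, n: int) -> tuple[list, list]:
    """The n tokens before and after ``position``, PAD-filled at the edges.

    ``before`` is left-padded (reading order preserved), ``after`` is
    right-padded; both always have length exactly ``n``. The window is
    confined to the sentence.
    """
    if n < 1:
        raise ValidationError(f"context size n must be >= 1, got {n}")
    if not 0 <= position < len(sentence):
        raise IndexError(
            f"position {position} out of range for sentence of length {len(sentence)}")
    before = sentence[max(0, position - n):position]
    after = sentence[position + 1:position + 1 + n]
    before = [PAD] * (n - len(before)) + list(before)
    after = list(after) + [PAD] * (n - len(after))
    return before, after


def assemble_examples(
    instances: Iterable[TokenInstance],
    tokens_by_review: Mapping[str, list[TaggedToken]],
    store: EmbeddingStore,
    n: int = 3,
) -> list[SequenceExample]:
    """Embed each instance's context window and target word.

    The context branch input is the concatenation before -> after (length
    2n); every vector comes from :meth:`EmbeddingStore.vector_for`, so PAD
    positions and (under the default policy) OOV words embed as zero.
    """
    sentences_cache: dict[str, dict[int, list[str]]] = {}
    examples: list[SequenceExample] = []
    for inst in instances:
        if inst.review_id not in sentences_cache:
            sentences_cache[inst.review_id] = {
                i: [t.surface.lower() for t in sent]
                for i, sent in sentence_words(tokens_by_review[inst.review_id]).items()
            }
        sentence = sentences_cache[inst.review_id][inst.sentence_index]
        before, after = extract_context(sentence, inst.filtered_position, n)
        context = store.matrix_for(before + after)
        word = store.vector_for(sentence[inst.filtered_position])
        examples.append(SequenceExample(context, word, inst.label, inst))
    return examples


def examples_to_arrays(
    examples: list[SequenceExample],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack examples into ``(X_context (N,2n,d), X_word (N,1,d), y (N,))``."""
    if not examples:
        raise ValidationError("cannot stack an empty example list")
    x_ctx = np.stack([e.context_vectors for e in examples]).astype(np.float32)
    x_word = np.stack([e.word_vector for e in examples]).astype(np.float32)[:, None, :]
    y = np.array([e.label for e in examples], dtype=np.int64)
    return x_ctx, x_word, y


def split_examples(
    examples: list[SequenceExample],
    test_fraction: float,
    seed: int,
    level: str = "instance",
) -> tuple[list[SequenceExample], list[SequenceExample]]:
    """Random train/test partition, reproducible for a fixed seed.

    ``level="instance"`` (default) partitions occurrences, so one word type
    may appear on both sides — the training protocol used here, which tends
    to flatter accuracy relative to ``level="type"``, where all occurrences
    of a word type land on the same side (offered for sensitivity analysis).
    ``|test| = round(test_fraction * N)`` at instance level; at type level it
    is matched as closely as whole types allow.
    """
    if not 0 < test_fraction < 1:
        raise ValidationError(f"test_fraction must be in (0,1), got {test_fraction}")
    if len(examples) < 2:
        raise ValidationError("need at least 2 examples to split")
    rng = np.random.default_rng(seed)
    n_test = round(test_fraction * len(examples))
    if level == "instance":
        order = rng.permutation(len(examples))
        test_idx = set(order[:n_test].tolist())
        train = [e for i, e in enumerate(examples) if i not in test_idx]
        test = [e for i, e in enumerate(examples) if i in test_idx]
        return train, test
    if level == "type":
        types = sorted({e.provenance.token_type for e in examples})
        order = rng.permutation(len(types))
        counts = {t: 0 for t in types}
        for e in examples:
            counts[e.provenance.token_type] += 1
        test_types: set[str] = set()
        total = 0
        for i in order:
            if total >= n_test:
                break
            test_types.add(types[i])
            total += counts[types[i]]
        train = [e for e in examples if e.provenance.token_type not in test_types]
        test = [e for e in examples if e.provenance.token_type in test_types]
        return train, test
    raise ValidationError(f"unknown split level {level!r}")


def type_overlap_fraction(train: list[SequenceExample],
                          test: list[SequenceExample]) -> float:
    """Fraction of test instances whose word type also occurs in training.

    A diagnostic for the instance-level protocol: values near 1 mean test
    accuracy largely reflects re-recognition of already-seen word types.
    """
    if not test:
        return 0.0
    train_types = {e.provenance.token_type for e in train}
    hits = sum(1 for e in test if e.provenance.token_type in train_types)
    return hits / len(test)


def class_ratio(examples: list[SequenceExample]) -> tuple[float, float]:
    """(descriptor fraction, non-descriptor fraction); sums to 1."""
    if not examples:
        raise ValidationError("class_ratio of an empty example list is undefined")
    pos = sum(e.label for e in examples) / len(examples)
    return pos, 1.0 - pos


def write_instance_table(instances: Iterable[TokenInstance], path: str | Path) -> None:
    """The bookkeeping table: one row per occurrence with its address."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["token_type", "review_id", "sentence_index", "position", "label"])
        for inst in instances:
            writer.writerow([inst.token_type, inst.review_id, inst.sentence_index,
                             inst.filtered_position, inst.label])


def read_instance_table(path: str | Path) -> list[TokenInstance]:
    need = {"token_type", "review_id", "sentence_index", "position", "label"}
    out: list[TokenInstance] = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not need <= set(reader.fieldnames):
            raise SchemaError(f"instance table {path} must have columns {sorted(need)}")
        for row in reader:
            out.append(TokenInstance(row["token_type"], row["review_id"],
                                     int(row["sentence_index"]), int(row["position"]),
                                     int(row["label"])))
    return out
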