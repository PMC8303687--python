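"""Review corpus I/O, tokenization, POS tagging, and candidate-lemma frequencies.

Reviews are plain CSV (one row per review). Tokenization and part-of-speech
tagging go through a pluggable provider so that a statistical tagger can be
bound in production while the test suite and synthetic corpora use the
deterministic :class:`RuleBasedTagger`. Candidate flavor descriptors are the
lemmas of nouns, adjectives, and an optional whitelist of verbs, counted into
a frequency table that drives annotation prioritization.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

from ._lexicon import DEFAULT_LEXICON
from .exceptions import SchemaError, TaggerError, ValidationError

__all__ = [
    "Review",
    "TaggedToken",
    "FrequencyTable",
    "PosTagger",
    "RuleBasedTagger",
    "read_reviews",
    "write_reviews",
    "segment_and_tag",
    "lemma_candidates",
    "write_frequency_table",
    "read_frequency_table",
]

#: Universal-tagset tags treated as punctuation by the position index.
PUNCT_TAG = "PUNCT"

_MANDATORY_COLUMNS = ("review_id", "text")
_STANDARD_COLUMNS = ("review_id", "source", "reviewer", "text")

_TOKEN_RE = re.compile(r"[A-Za-z0-9']+|[^\sA-Za-z0-9']")
_SENTENCE_RE = re.compile(r"(?<=[.!?])\s+")


@dataclass(frozen=True)
class Review:
    """One full-text review plus provenance metadata (title excluded)."""

    review_id: str
    text: str
    source: str = ""
    reviewer: str = ""
    metadata: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class TaggedToken:
    """A single token with POS, lemma, and its two position systems.

    ``raw_position`` counts every token in the sentence including punctuation;
    ``filtered_position`` counts only non-punctuation tokens (``None`` for
    punctuation) and is the coordinate used by context windows.
    """

    surface: str
    pos: str
    lemma: str
    sentence_index: int
    raw_position: int
    filtered_position: int | None

    @property
    def is_punct(self) -> bool:
        return self.pos == PUNCT_TAG


@dataclass
class FrequencyTable:
    """Lemma -> occurrence count over NOUN/ADJ/whitelisted-VERB tokens."""

    entries: Counter = field(default_factory=Counter)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, lemma: str) -> int:
        return self.entries[lemma]

    def merge(self, other: "FrequencyTable") -> "FrequencyTable":
        """Pool counts with another table (e.g., across review sites)."""
        merged = Counter(self.entries)
        merged.update(other.entries)
        return FrequencyTable(merged)

    def sorted_lemmas(self) -> list[str]:
        """Count-descending order, ties broken lexicographically ascending."""
        return sorted(self.entries, key=lambda w: (-self.entries[w], w))


class PosTagger(Protocol):
    """Provider contract: sentence segmentation plus per-token (pos, lemma).

    Implementations must be deterministic for a fixed model or ruleset so
    that annotation-time lemmas match classification-time lemmas.
    """

    def split_sentences(self, text: str) -> list[str]: ...

    def tag(self, surface: str) -> tuple[str, str]:
        """Return ``(pos, lemma)`` for one non-punctuation token."""
        ...


class RuleBasedTagger:
    """Deterministic dictionary + suffix-rule tagger.

    Lemmatization tries, in order: exact lexicon hit; plural ``-ies`` -> ``-y``
    and ``-s`` stripping; ``-ing``/``-ed`` stripping (with final-e restoration
    and undoubling) checked against the lexicon. Inflected verb forms found by
    the ``-ing``/``-ed`` rules are tagged VERB regardless of the base lemma's
    own tag ("drying" -> VERB, lemma "dry"). Unknown words default to NOUN,
    the open-class majority for review text.
    """

    def __init__(self, lexicon: Mapping[str, str] | None = None,
                 unknown_pos: str = "NOUN"):
        self.lexicon = dict(DEFAULT_LEXICON if lexicon is None else lexicon)
        self.unknown_pos = unknown_pos

    def split_sentences(self, text: str) -> list[str]:
        return [s for s in _SENTENCE_RE.split(text.strip()) if s]

    def tag(self, surface: str) -> tuple[str, str]:
        word = surface.lower()
        if word in self.lexicon:
            return self.lexicon[word], word
        # plural nouns
        if word.endswith("ies") and word[:-3] + "y" in self.lexicon:
            base = word[:-3] + "y"
            return self.lexicon[base], base
        if word.endswith("s") and not word.endswith("ss") and word[:-1] in self.lexicon:
            base = word[:-1]
            return self.lexicon[base], base
        # verbal inflections: -ing / -ed with e-restoration and undoubling
        for suffix in ("ing", "ed"):
            if word.endswith(suffix) and len(word) > len(suffix) + 1:
                stem = word[: -len(suffix)]
                for base in (stem, stem + "e",
                             stem[:-1] if len(stem) > 2 and stem[-1] == stem[-2] else None):
                    if base and base in self.lexicon:
                        return "VERB", base
        return self.unknown_pos, word


def read_reviews(path: str | Path, dialect: str = "excel") -> list[Review]:
    """Read a reviews CSV into :class:`Review` records, preserving row order.

    The header must contain at least ``review_id`` and ``text``; any column
    outside the standard four is captured verbatim into ``metadata``.

    Raises
    ------
    SchemaError
        If a mandatory column is absent.
    ValidationError
        If a ``review_id`` occurs twice.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, dialect=dialect)
        header = reader.fieldnames or []
        for col in _MANDATORY_COLUMNS:
            if col not in header:
                raise SchemaError(f"reviews CSV {path} is missing mandatory column {col!r}")
        extra = [c for c in header if c not in _STANDARD_COLUMNS]
        reviews: list[Review] = []
        seen: set[str] = set()
        for row in reader:
            rid = row["review_id"]
            if rid in seen:
                raise ValidationError(f"duplicate review_id {rid!r} in {path}")
            seen.add(rid)
            reviews.append(Review(
                review_id=rid,
                text=row.get("text") or "",
                source=row.get("source") or "",
                reviewer=row.get("reviewer") or "",
                metadata={c: row.get(c) or "" for c in extra},
            ))
    return reviews


def write_reviews(reviews: Iterable[Review], path: str | Path) -> None:
    """Write reviews to CSV (RFC-4180 quoting), standard columns first."""
    reviews = list(reviews)
    extra_cols: list[str] = []
    for r in reviews:
        for c in r.metadata:
            if c not in extra_cols:
                extra_cols.append(c)
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(_STANDARD_COLUMNS) + extra_cols)
        for r in reviews:
            writer.writerow([r.review_id, r.source, r.reviewer, r.text]
                            + [r.metadata.get(c, "") for c in extra_cols])


def tokenize(sentence: str) -> list[str]:
    """Split a sentence into word and single-character punctuation tokens."""
    return _TOKEN_RE.findall(sentence)


def segment_and_tag(review: Review, tagger: PosTagger | None = None) -> list[TaggedToken]:
    """Tokenize a review into POS-tagged sentences.

    Tokens are ordered by ``(sentence_index, raw_position)``; punctuation is
    tagged PUNCT and excluded from the filtered position index, which runs
    contiguously from 0 over the remaining tokens of each sentence.
    """
    tagger = tagger or RuleBasedTagger()
    out: list[TaggedToken] = []
    for s_idx, sentence in enumerate(tagger.split_sentences(review.text)):
        try:
            surfaces = tokenize(sentence)
            filtered = 0
            for raw_pos, surface in enumerate(surfaces):
                if not surface[0].isalnum() and not surface[0] == "'":
                    out.append(TaggedToken(surface, PUNCT_TAG, surface,
                                           s_idx, raw_pos, None))
                    continue
                pos, lemma = tagger.tag(surface)
                out.append(TaggedToken(surface, pos, lemma, s_idx, raw_pos, filtered))
                filtered += 1
        except Exception as exc:  # pragma: no cover - provider failures
            raise TaggerError(f"tagger failed: {exc}", review.review_id, s_idx) from exc
    return out


def lemma_candidates(tokens: Iterable[TaggedToken],
                     verb_whitelist: Iterable[str] = ()) -> FrequencyTable:
    """Count candidate-descriptor lemmas: nouns, adjectives, whitelisted verbs.

    All other parts of speech are excluded. Keys are lowercase lemmas, so
    surface variants ("drying", "dried") pool under one entry ("dry").
    """
    whitelist = {w.lower() for w in verb_whitelist}
    counts: Counter = Counter()
    for tok in tokens:
        if tok.pos in ("NOUN", "ADJ") or (tok.pos == "VERB" and tok.lemma in whitelist):
            counts[tok.lemma.lower()] += 1
    return FrequencyTable(counts)


def write_frequency_table(table: FrequencyTable, path: str | Path) -> None:
    """Write ``lemma,count`` CSV sorted count-descending then lemma-ascending."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["lemma", "count"])
        for lemma in table.sorted_lemmas():
            writer.writerow([lemma, table.entries[lemma]])


def read_frequency_table(path: str | Path) -> FrequencyTable:
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"lemma", "count"} <= set(reader.fieldnames):
            raise SchemaError(f"frequency CSV {path} must have columns lemma,count")
        return FrequencyTable(Counter({row["lemma"]: int(row["count"]) for row in reader}))
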