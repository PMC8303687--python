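"""Annotation-queue logic, multi-annotator consensus, and label projection.

Human annotators label candidate *lemmas* as descriptor (1) or non-descriptor
(0) in frequency-prioritized batches. A lemma's final label is decided by a
two-of-three consensus vote; the lemma label is then projected onto every
distinct surface token type that lemmatizes to it, since one lemma ("fruit")
can surface as several token types ("fruity", "fruits").
"""

from __future__ import annotations

import csv
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from pathlib import Path

from .corpus import TaggedToken
from .exceptions import LabelConflictError, SchemaError, ValidationError

__all__ = [
    "AnnotatorLabel",
    "ConsensusRecord",
    "LabeledTokenType",
    "build_annotation_queue",
    "merge_consensus",
    "project_labels_to_tokens",
    "read_annotator_csv",
    "write_annotation_page",
    "write_consensus_csv",
    "read_consensus_csv",
]


@dataclass(frozen=True)
class AnnotatorLabel:
    lemma: str
    annotator_id: str
    label: int


@dataclass(frozen=True)
class ConsensusRecord:
    """A lemma with its per-annotator votes and the consensus label."""

    lemma: str
    votes: Mapping[str, int]
    final_label: int

    @property
    def n_votes(self) -> int:
        return len(self.votes)

    @property
    def n_positive(self) -> int:
        return sum(self.votes.values())


@dataclass(frozen=True)
class LabeledTokenType:
    """A case-folded surface word type carrying its source lemma's label."""

    token_type: str
    source_lemma: str
    label: int


def build_annotation_queue(table, page_size: int) -> list[list[str]]:
    """Page lemmas for annotation, most frequent first.

    Ordering is count-descending with lexicographic tie-break, so the queue
    is a stable total order; pages hold at most ``page_size`` lemmas and
    concatenate back to the full ordering.
    """
    if page_size < 1:
        raise ValidationError(f"page_size must be >= 1, got {page_size}")
    ordered = table.sorted_lemmas()
    return [ordered[i:i + page_size] for i in range(0, len(ordered), page_size)]


def merge_consensus(
    votes: Iterable[AnnotatorLabel] | Mapping[str, Mapping[str, int]],
) -> dict[str, ConsensusRecord]:
    """Apply the two-of-three rule: descriptor iff >= 2 positive votes.

    The rule is fixed at two positive votes regardless of how many annotators
    voted, so a single positive vote never yields a descriptor and with two
    annotators a (1, 0) tie resolves to non-descriptor.
    """
    by_lemma: dict[str, dict[str, int]] = {}
    if isinstance(votes, Mapping):
        for lemma, per_annotator in votes.items():
            by_lemma[lemma] = dict(per_annotator)
    else:
        for v in votes:
            by_lemma.setdefault(v.lemma, {})[v.annotator_id] = v.label
    records: dict[str, ConsensusRecord] = {}
    for lemma, per_annotator in by_lemma.items():
        for annotator, label in per_annotator.items():
            if label not in (0, 1):
                raise ValidationError(
                    f"non-binary vote {label!r} from annotator {annotator!r} "
                    f"on lemma {lemma!r}")
        final = 1 if sum(per_annotator.values()) >= 2 else 0
        records[lemma] = ConsensusRecord(lemma, dict(per_annotator), final)
    return records


def project_labels_to_tokens(
    records: Mapping[str, ConsensusRecord] | Iterable[ConsensusRecord],
    corpus_tokens: Iterable[TaggedToken],
) -> dict[str, LabeledTokenType]:
    """Project consensus lemma labels onto every surface token type.

    Every distinct case-folded, non-punctuation surface form whose lemma has
    a consensus record inherits that record's final label. A surface form
    whose occurrences lemmatize to two differently-labeled lemmas is a
    conflict and raises :class:`LabelConflictError` naming the pair.
    """
    if not isinstance(records, Mapping):
        records = {r.lemma: r for r in records}
    out: dict[str, LabeledTokenType] = {}
    for tok in corpus_tokens:
        if tok.is_punct:
            continue
        rec = records.get(tok.lemma.lower())
        if rec is None:
            continue
        token_type = tok.surface.lower()
        prev = out.get(token_type)
        if prev is not None:
            if prev.label != rec.final_label:
                raise LabelConflictError(
                    f"token type {token_type!r} maps to lemma {prev.source_lemma!r} "
                    f"(label {prev.label}) and lemma {rec.lemma!r} "
                    f"(label {rec.final_label})")
            continue
        out[token_type] = LabeledTokenType(token_type, rec.lemma, rec.final_label)
    return out


def write_annotation_page(lemmas: Iterable[str], path: str | Path) -> None:
    """Write one queue page as an annotator worksheet (label column empty)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["lemma", "label"])
        for lemma in lemmas:
            writer.writerow([lemma, ""])


def read_annotator_csv(path: str | Path, annotator_id: str) -> list[AnnotatorLabel]:
    """Read one annotator's ``lemma,label`` CSV; blank labels are skipped."""
    labels: list[AnnotatorLabel] = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"lemma", "label"} <= set(reader.fieldnames):
            raise SchemaError(f"annotator CSV {path} must have columns lemma,label")
        for row in reader:
            raw = (row["label"] or "").strip()
            if raw == "":
                continue
            if raw not in ("0", "1"):
                raise ValidationError(
                    f"non-binary label {raw!r} for lemma {row['lemma']!r} in {path}")
            labels.append(AnnotatorLabel(row["lemma"], annotator_id, int(raw)))
    return labels


def write_consensus_csv(records: Mapping[str, ConsensusRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["lemma", "final_label", "n_votes", "n_positive"])
        for lemma in sorted(records):
            rec = records[lemma]
            writer.writerow([lemma, rec.final_label, rec.n_votes, rec.n_positive])


def read_consensus_csv(path: str | Path) -> dict[str, ConsensusRecord]:
    """Read a consensus CSV back; individual votes are not reconstructed."""
    out: dict[str, ConsensusRecord] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        need = {"lemma", "final_label"}
        if reader.fieldnames is None or not need <= set(reader.fieldnames):
            raise SchemaError(f"consensus CSV {path} must have columns lemma,final_label")
        for row in reader:
            out[row["lemma"]] = ConsensusRecord(
                row["lemma"], {}, int(row["final_label"]))
    return out
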