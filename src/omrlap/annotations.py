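"""Annotation data model and I/O.

The unit of analysis is a *concept mention*: one row per concept an NLP
engine extracted from a document, carrying patient/document/date context,
the normalized surface term, its coarse semantic group(s), and contextual
attributes (experiencer, assertion).  Concept *identity* is the triple
(term, semantic group, patient id) — the same term annotated with two
different semantic groups in different mentions yields two distinct
concepts, while a single mention tagged with a compound group such as
"CHEM;DRUG" yields one concept with the joint group.

Two on-disk formats are supported:

* ``delimited`` — UTF-8 tab-separated with a header row, columns exactly
  ``patient_id, document_id, corpus_tag, note_date, section, term, cui,
  semantic_group, experiencer, assertion``;
* ``record-stream`` — one JSON object per line with the same field names.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "SEMANTIC_CODES",
    "SECTIONS",
    "CORPUS_TAGS",
    "SchemaError",
    "ValidationError",
    "AnnotationRecord",
    "ConceptKey",
    "ConceptSet",
    "canonical_semantic_group",
    "normalize_term",
    "read_annotations",
    "write_annotations",
    "filter_patient_experiencer",
    "build_concept_set",
]

#: Coarse semantic-category codes (UMLS semantic-group style).
SEMANTIC_CODES = frozenset(
    {"ACTI", "ANAT", "CHEM", "CONC", "DISO", "DRUG", "FIND", "PROC"}
)

#: The 12 structured note sections of the consultant notes, plus UNKNOWN
#: for documents (scanned outside records) with no section structure.
SECTIONS = (
    "Allergy",
    "Chief Complaint and reason for visit",
    "Current Medications",
    "Diagnosis",
    "Family History",
    "History of present illness",
    "Impression/report/plan",
    "Past medical and surgical history",
    "Physical Exam",
    "Social History",
    "System Review",
    "Vital Signs",
    "UNKNOWN",
)

CORPUS_TAGS = ("OMR", "CN", "ECN")

COLUMNS = (
    "patient_id",
    "document_id",
    "corpus_tag",
    "note_date",
    "section",
    "term",
    "cui",
    "semantic_group",
    "experiencer",
    "assertion",
)


class SchemaError(ValueError):
    """An annotation file does not match the documented column schema."""


class ValidationError(ValueError):
    """A row carries a value outside the documented vocabulary."""


def normalize_term(term: str) -> str:
    """Case-fold and whitespace-collapse a surface term.

    The NLP engine already emits normalized/preferred terms; this is a
    guard against incidental casing or spacing drift, not re-normalization
    of semantics (no stemming, no synonym folding).
    """
    return " ".join(term.casefold().split())


def canonical_semantic_group(group: str) -> str:
    """Canonicalize a semicolon-joined semantic-group value.

    Splits on ";", strips, dedupes and sorts, so ``"DRUG;CHEM"`` becomes
    ``"CHEM;DRUG"``.  Idempotent.  Raises :class:`ValidationError` on an
    empty value or a code outside :data:`SEMANTIC_CODES`.
    """
    codes = sorted({c.strip().upper() for c in group.split(";") if c.strip()})
    if not codes:
        raise ValidationError("semantic_group must be non-empty")
    unknown = [c for c in codes if c not in SEMANTIC_CODES]
    if unknown:
        raise ValidationError(f"unknown semantic code(s) {unknown!r} in {group!r}")
    return ";".join(codes)


@dataclass(frozen=True, order=True)
class ConceptKey:
    """The unit of concept uniqueness: term + semantic group + patient."""

    term: str
    semantic_group: str
    patient_id: str

    def render(self) -> str:
        return f"{self.term}::{self.semantic_group}::{self.patient_id}"

    @property
    def type_key(self) -> tuple[str, str]:
        """The patient-free (term, semantic_group) pair used for
        terminology lookups and population-level frequency profiles."""
        return (self.term, self.semantic_group)


@dataclass(frozen=True)
class AnnotationRecord:
    """One extracted concept mention with its document context."""

    patient_id: str
    document_id: str
    corpus_tag: str
    note_date: dt.date | None
    section: str
    term: str
    cui: str | None
    semantic_group: str
    experiencer: str
    assertion: str = ""

    def __post_init__(self) -> None:
        if self.corpus_tag not in CORPUS_TAGS:
            raise ValidationError(
                f"corpus_tag must be one of {CORPUS_TAGS}, got {self.corpus_tag!r}"
            )
        object.__setattr__(self, "term", normalize_term(self.term))
        object.__setattr__(
            self, "semantic_group", canonical_semantic_group(self.semantic_group)
        )
        if not self.section:
            object.__setattr__(self, "section", "UNKNOWN")

    @property
    def concept_key(self) -> ConceptKey:
        return ConceptKey(self.term, self.semantic_group, self.patient_id)


@dataclass(frozen=True)
class ConceptSet:
    """A labelled set of unique concepts drawn from one corpus."""

    label: str
    members: frozenset[ConceptKey] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, key: ConceptKey) -> bool:
        return key in self.members

    def __or__(self, other: "ConceptSet") -> "ConceptSet":
        return ConceptSet(
            f"{self.label}|{other.label}", self.members | other.members
        )

    def relabel(self, label: str) -> "ConceptSet":
        return replace(self, label=label)


def _parse_date(value: str) -> dt.date | None:
    # Unparseable dates yield an absent date, never a failure: scanned
    # outside records routinely lack usable date stamps.
    value = value.strip()
    if not value:
        return None
    try:
        return dt.date.fromisoformat(value)
    except ValueError:
        return None


def _record_from_mapping(row: dict, lineno: int) -> AnnotationRecord:
    missing = [c for c in COLUMNS if c not in row]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    try:
        return AnnotationRecord(
            patient_id=str(row["patient_id"]),
            document_id=str(row["document_id"]),
            corpus_tag=str(row["corpus_tag"]),
            note_date=_parse_date(str(row["note_date"] or "")),
            section=str(row["section"] or "UNKNOWN"),
            term=str(row["term"]),
            cui=(str(row["cui"]) or None) if row["cui"] else None,
            semantic_group=str(row["semantic_group"]),
            experiencer=str(row["experiencer"]),
            assertion=str(row["assertion"] or ""),
        )
    except ValidationError as exc:
        raise ValidationError(f"row {lineno}: {exc}") from exc


def read_annotations(
    path: str | Path, format: str = "delimited"
) -> list[AnnotationRecord]:
    """Read annotation records from ``path``.

    ``format`` is ``"delimited"`` (TSV with header) or ``"record-stream"``
    (one JSON object per line).  Every row becomes a record; the semantic
    group is canonicalized on ingestion.
    """
    path = Path(path)
    records: list[AnnotationRecord] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        if format == "delimited":
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames is None:
                return records
            missing = [c for c in COLUMNS if c not in reader.fieldnames]
            if missing:
                raise SchemaError(
                    f"{path}: missing mandatory column(s): {', '.join(missing)}"
                )
            for lineno, row in enumerate(reader, start=2):
                records.append(_record_from_mapping(row, lineno))
        elif format == "record-stream":
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                records.append(_record_from_mapping(json.loads(line), lineno))
        else:
            raise ValueError(f"unknown format {format!r}")
    return records


def write_annotations(
    records: Iterable[AnnotationRecord],
    path: str | Path,
    format: str = "delimited",
) -> None:
    """Write records to ``path`` in a format :func:`read_annotations` reads
    back field-for-field."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        if format == "delimited":
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(COLUMNS)
            for r in records:
                writer.writerow(_row_of(r))
        elif format == "record-stream":
            for r in records:
                fh.write(json.dumps(dict(zip(COLUMNS, _row_of(r))), sort_keys=True))
                fh.write("\n")
        else:
            raise ValueError(f"unknown format {format!r}")


def _row_of(r: AnnotationRecord) -> tuple:
    return (
        r.patient_id,
        r.document_id,
        r.corpus_tag,
        r.note_date.isoformat() if r.note_date else "",
        r.section,
        r.term,
        r.cui or "",
        r.semantic_group,
        r.experiencer,
        r.assertion,
    )


def filter_patient_experiencer(
    records: Sequence[AnnotationRecord],
) -> list[AnnotationRecord]:
    """Keep exactly the mentions whose experiencer is the patient.

    Mentions about other people ("His father had a history of heart
    attack") describe family history, not the referred patient's own
    state, and are excluded from every downstream statistic.
    """
    return [r for r in records if r.experiencer == "Patient"]


def build_concept_set(
    records: Sequence[AnnotationRecord], label: str
) -> ConceptSet:
    """Collapse mentions to the set of distinct concept keys.

    A mention observed 100 times contributes one member; a term annotated
    with two semantic groups contributes two members.  Records are assumed
    to be experiencer-filtered already.
    """
    return ConceptSet(label, frozenset(r.concept_key for r in records))
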