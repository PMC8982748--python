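"""Corpus assignment: reference dates, initial encounters, ICN/FCN split.

Scanned outside records rarely carry a reliable machine-readable date, so
each patient's *reference date* is resolved from expert-populated metadata
when available, falling back to the PDF creation dates.  The patient's
*initial encounter* is the first in-house note strictly after that
reference date; notes on the encounter day form the initial-consultant-
note (ICN) corpus and notes 1–90 days later form the follow-up (FCN)
corpus.  Everything else is left unassigned and counted.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotations import AnnotationRecord

__all__ = [
    "FOLLOWUP_WINDOW_DAYS",
    "UnresolvablePatientError",
    "PatientTimeline",
    "EncounterAssignment",
    "read_metadata",
    "build_timelines",
    "resolve_reference_date",
    "resolve_initial_encounter",
    "assign_note_corpus",
    "assign_all",
    "split_cn_records",
]

#: Default follow-up window: notes 1..90 days after the initial encounter.
FOLLOWUP_WINDOW_DAYS = 90


class UnresolvablePatientError(ValueError):
    """No reference date could be resolved for a patient."""

    def __init__(self, patient_id: str):
        self.patient_id = patient_id
        super().__init__(f"no reference date resolvable for patient {patient_id}")


@dataclass
class PatientTimeline:
    patient_id: str
    omr_dates: list[dt.date] = field(default_factory=list)
    pdf_creation_dates: list[dt.date] = field(default_factory=list)
    #: (document_id, date) pairs for in-house notes, sorted ascending by date.
    mayo_note_dates: list[tuple[str, dt.date]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mayo_note_dates.sort(key=lambda pair: (pair[1], pair[0]))


@dataclass
class EncounterAssignment:
    patient_id: str
    reference_date: dt.date
    initial_encounter_date: dt.date | None
    icn_documents: frozenset[str] = frozenset()
    fcn_documents: frozenset[str] = frozenset()
    unassigned_documents: frozenset[str] = frozenset()


def resolve_reference_date(timeline: PatientTimeline) -> dt.date:
    """Latest expert-metadata date; PDF creation dates as fallback."""
    if timeline.omr_dates:
        return max(timeline.omr_dates)
    if timeline.pdf_creation_dates:
        return max(timeline.pdf_creation_dates)
    raise UnresolvablePatientError(timeline.patient_id)


def resolve_initial_encounter(
    timeline: PatientTimeline, reference: dt.date
) -> dt.date | None:
    """Earliest in-house note date strictly after the reference date.

    Returns ``None`` when no note follows the reference date; such
    patients are excluded downstream with a logged count.
    """
    for _doc, date in timeline.mayo_note_dates:
        if date > reference:
            return date
    return None


def assign_note_corpus(
    timeline: PatientTimeline,
    initial: dt.date,
    window_days: int = FOLLOWUP_WINDOW_DAYS,
    reference: dt.date | None = None,
) -> EncounterAssignment:
    """Split a patient's notes into ICN / FCN / unassigned.

    Notes dated exactly on the initial encounter are ICN (several per
    patient allowed — one patient may visit multiple practice settings
    that day); notes 1..``window_days`` days after are FCN; anything
    earlier or later is unassigned.
    """
    icn: set[str] = set()
    fcn: set[str] = set()
    other: set[str] = set()
    for doc, date in timeline.mayo_note_dates:
        delta = (date - initial).days
        if delta == 0:
            icn.add(doc)
        elif 1 <= delta <= window_days:
            fcn.add(doc)
        else:
            other.add(doc)
    return EncounterAssignment(
        patient_id=timeline.patient_id,
        reference_date=reference if reference is not None else initial,
        initial_encounter_date=initial,
        icn_documents=frozenset(icn),
        fcn_documents=frozenset(fcn),
        unassigned_documents=frozenset(other),
    )


def read_metadata(path: str | Path) -> list[tuple[str, str, str, dt.date]]:
    """Read the metadata sidecar.

    TSV with header ``patient_id, document_id, source, date`` where
    ``source`` is ``expert_metadata`` or ``pdf_creation``.
    """
    rows: list[tuple[str, str, str, dt.date]] = []
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            rows.append(
                (
                    row["patient_id"],
                    row["document_id"],
                    row["source"],
                    dt.date.fromisoformat(row["date"]),
                )
            )
    return rows


def build_timelines(
    metadata: Iterable[tuple[str, str, str, dt.date]],
    cn_records: Sequence[AnnotationRecord],
) -> dict[str, PatientTimeline]:
    """Assemble per-patient timelines from metadata rows and CN records."""
    timelines: dict[str, PatientTimeline] = {}

    def get(pid: str) -> PatientTimeline:
        if pid not in timelines:
            timelines[pid] = PatientTimeline(pid)
        return timelines[pid]

    for pid, _doc, source, date in metadata:
        tl = get(pid)
        if source == "expert_metadata":
            tl.omr_dates.append(date)
        elif source == "pdf_creation":
            tl.pdf_creation_dates.append(date)
        else:
            raise ValueError(f"unknown metadata source {source!r}")

    seen: set[tuple[str, str]] = set()
    for r in cn_records:
        if r.corpus_tag != "CN" or r.note_date is None:
            continue
        if (r.patient_id, r.document_id) in seen:
            continue
        seen.add((r.patient_id, r.document_id))
        get(r.patient_id).mayo_note_dates.append((r.document_id, r.note_date))
    for tl in timelines.values():
        tl.mayo_note_dates.sort(key=lambda pair: (pair[1], pair[0]))
    return timelines


@dataclass
class AssignmentReport:
    """Bookkeeping for patients/notes that fall out of the ICN/FCN split."""

    assignments: dict[str, EncounterAssignment]
    unresolvable_patients: list[str]
    no_initial_encounter: list[str]
    unassigned_notes: int
    patients_with_prior_notes: int


def assign_all(
    timelines: Mapping[str, PatientTimeline],
    window_days: int = FOLLOWUP_WINDOW_DAYS,
) -> AssignmentReport:
    """Run reference-date resolution and the ICN/FCN split per patient."""
    assignments: dict[str, EncounterAssignment] = {}
    unresolvable: list[str] = []
    no_initial: list[str] = []
    unassigned_notes = 0
    prior = 0
    for pid in sorted(timelines):
        tl = timelines[pid]
        try:
            reference = resolve_reference_date(tl)
        except UnresolvablePatientError:
            unresolvable.append(pid)
            continue
        initial = resolve_initial_encounter(tl, reference)
        if initial is None:
            no_initial.append(pid)
            continue
        a = assign_note_corpus(tl, initial, window_days, reference=reference)
        assignments[pid] = a
        unassigned_notes += len(a.unassigned_documents)
        if any(date < initial for _d, date in tl.mayo_note_dates):
            prior += 1
    return AssignmentReport(
        assignments=assignments,
        unresolvable_patients=unresolvable,
        no_initial_encounter=no_initial,
        unassigned_notes=unassigned_notes,
        patients_with_prior_notes=prior,
    )


def split_cn_records(
    records: Sequence[AnnotationRecord],
    assignments: Mapping[str, EncounterAssignment],
) -> tuple[list[AnnotationRecord], list[AnnotationRecord], list[AnnotationRecord]]:
    """Partition CN records into (ICN, FCN, dropped) by document id."""
    icn: list[AnnotationRecord] = []
    fcn: list[AnnotationRecord] = []
    dropped: list[AnnotationRecord] = []
    for r in records:
        if r.corpus_tag != "CN":
            continue
        a = assignments.get(r.patient_id)
        if a is None:
            dropped.append(r)
        elif r.document_id in a.icn_documents:
            icn.append(r)
        elif r.document_id in a.fcn_documents:
            fcn.append(r)
        else:
            dropped.append(r)
    return icn, fcn, dropped
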