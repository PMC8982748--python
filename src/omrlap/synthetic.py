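"""Synthetic annotation corpora with planted ground truth.

Real referral corpora (scanned outside records plus in-house consultant
notes) are private, so every pipeline stage is exercised on generated
data whose structure is known by construction:

* per-patient concept sets whose seven-region Venn cardinalities are
  planted *exactly* (a concept's region decides which corpora mention it);
* a multi-type semantic-group distribution, with per-group counts
  plantable per overlap region so coverage tables are reproducible;
* note dates built so the reference-date / initial-encounter / 90-day
  follow-up machinery produces the intended ICN/FCN split, including the
  day-90 boundary;
* a configurable fraction of mentions with experiencer "Others" that the
  pipeline must filter out (their terms are disjoint from the planted
  sets, so a missing filter changes the counts);
* a random is-a terminology tree with synonym surface terms, and
  "near match" plants: a fraction of OMR-only concepts whose terms map
  one edge away from a note-corpus concept, giving the flexible matcher
  path-similarity 0.5 candidates;
* a two-corpus (specialty vs. all-practice) mention-frequency profile
  with planted per-region mapping rates and score sums, and planted
  specialty-exclusive concepts (score exactly 1).

Identical seeds produce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotations import (
    SECTIONS,
    AnnotationRecord,
    write_annotations,
)
from .saliency import FrequencyProfile
from .terminology import TerminologyGraph, save_terminology

__all__ = ["SyntheticSpec", "SpecError", "GeneratedCorpora", "generate_terminology", "generate_corpora"]

REGION_LABELS = ("A", "B", "C", "D", "E", "F", "G")

#: Which corpora mention a concept, by region.
REGION_MEMBERSHIP = {
    "A": ("OMR", "ICN", "FCN"),
    "B": ("OMR", "ICN"),
    "C": ("OMR", "FCN"),
    "D": ("ICN", "FCN"),
    "E": ("ICN",),
    "F": ("FCN",),
    "G": ("OMR",),
}

# Study-condition defaults: the corpus-level region cardinalities, the
# per-region semantic-group frequencies of the overlap regions, the
# semantic-group mix of the overlap union, the per-region background
# mapping rates and saliency-score sums of the reference cardiovascular
# referral cohort this generator emulates.
DEFAULT_REGION_CARDINALITIES = {
    "A": 4793,
    "B": 14371,
    "C": 6745,
    "D": 6050,
    "E": 34947,
    "F": 23660,
    "G": 141013,
}

DEFAULT_REGION_GROUP_COUNTS = {
    "A": {
        "FIND": 1825, "PROC": 962, "DISO": 860, "ANAT": 408,
        "CHEM;DRUG": 511, "DRUG": 217, "CHEM": 6, "ACTI": 2, "CONC": 2,
    },
    "B": {
        "FIND": 5917, "PROC": 3178, "DISO": 2325, "ANAT": 1364,
        "CHEM;DRUG": 1022, "DRUG": 504, "CHEM": 37, "ACTI": 12, "CONC": 12,
    },
    "C": {
        "FIND": 2737, "PROC": 1495, "DISO": 1052, "ANAT": 813,
        "CHEM;DRUG": 412, "DRUG": 200, "CHEM": 22, "ACTI": 7, "CONC": 7,
    },
}

DEFAULT_GROUP_WEIGHTS = {
    "FIND": 0.4045,
    "PROC": 0.2175,
    "DISO": 0.1635,
    "ANAT": 0.0998,
    "CHEM;DRUG": 0.0751,
    "DRUG": 0.0355,
    "CHEM": 0.0025,
    "ACTI": 0.0008,
    "CONC": 0.0008,
}

# Section mix: the stated shares for the five dominant sections; the
# remainder spread uniformly over the other seven structured sections.
_STATED_SECTIONS = {
    "Impression/report/plan": 0.3188,
    "History of present illness": 0.2719,
    "Physical Exam": 0.1189,
    "Diagnosis": 0.0542,
    "Current Medications": 0.0482,
}
DEFAULT_SECTION_WEIGHTS = dict(_STATED_SECTIONS)
_rest = [s for s in SECTIONS if s not in _STATED_SECTIONS and s != "UNKNOWN"]
for _s in _rest:
    DEFAULT_SECTION_WEIGHTS[_s] = (1.0 - sum(_STATED_SECTIONS.values())) / len(_rest)

DEFAULT_MAPPED_RATES = {
    "A": 0.9971, "B": 0.9977, "C": 0.9987, "D": 0.9916,
    "E": 0.9866, "F": 0.9695, "G": 0.9315,
}

DEFAULT_SCORE_SUMS = {
    "A": 411.25, "B": 1266.28, "C": 431.34, "D": 484.62,
    "E": 3232.15, "F": 1443.17, "G": 8219.96,
}


class SpecError(ValueError):
    """The synthetic specification is internally inconsistent."""


@dataclass
class SyntheticSpec:
    """Knobs of the generator; the defaults are the study conditions of
    the reference referral cohort (294 patients, the printed region
    cardinalities and semantic-group tables)."""

    seed: int = 0
    n_patients: int = 294
    region_cardinalities: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_REGION_CARDINALITIES)
    )
    #: Exact per-group counts for regions (missing regions fall back to
    #: semantic_group_weights draws).
    region_group_counts: dict[str, dict[str, int]] | None = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_REGION_GROUP_COUNTS.items()}
    )
    semantic_group_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_WEIGHTS)
    )
    section_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SECTION_WEIGHTS)
    )
    #: Mean of the Poisson number of *extra* duplicate mentions emitted per
    #: concept-corpus incidence (duplicates never change the concept sets).
    mention_extra_mean: float = 0.2
    #: Fraction of additional mentions carrying experiencer "Others".
    others_fraction: float = 0.05
    #: Fraction of patients given an in-house note predating the reference
    #: date (its mentions duplicate already-planted ICN concepts).
    prior_note_fraction: float = 0.1
    #: Fraction of patients whose reference date must come from PDF
    #: creation dates (no expert metadata).
    pdf_fallback_fraction: float = 0.2
    # terminology
    n_terminology_concepts: int = 500
    branching: int = 3
    extra_edge_fraction: float = 0.05
    synonym_fraction: float = 0.1
    #: Fraction of OMR-only (region G) concepts whose term is planted one
    #: is-a edge away from a note-corpus concept's term.
    near_match_fraction: float = 0.1
    # background frequency profile
    region_mapped_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MAPPED_RATES)
    )
    region_score_sums: dict[str, float] | None = field(
        default_factory=lambda: dict(DEFAULT_SCORE_SUMS)
    )
    #: Number of planted specialty-exclusive concepts (score exactly 1),
    #: taken from region E.
    n_specialty_exclusive: int = 25
    #: Common all-practice denominator used for planted score sums.
    background_denominator: int = 1_000_000

    def validate(self) -> None:
        if self.n_patients < 1:
            raise SpecError("n_patients must be >= 1")
        if set(self.region_cardinalities) != set(REGION_LABELS):
            raise SpecError("region_cardinalities must cover exactly regions A..G")
        for label, n in self.region_cardinalities.items():
            if n < 0:
                raise SpecError(f"region {label} cardinality must be non-negative")
        if self.region_group_counts:
            for label, groups in self.region_group_counts.items():
                want = self.region_cardinalities[label]
                got = sum(groups.values())
                if got != want:
                    raise SpecError(
                        f"region {label}: group counts sum to {got}, "
                        f"cardinality is {want}"
                    )
        for name, weights in (
            ("semantic_group_weights", self.semantic_group_weights),
            ("section_weights", self.section_weights),
        ):
            total = sum(weights.values())
            if abs(total - 1.0) > 1e-6:
                raise SpecError(f"{name} must sum to 1, got {total}")
            if any(w < 0 for w in weights.values()):
                raise SpecError(f"{name} must be non-negative")
        if not 0.0 <= self.near_match_fraction <= 1.0:
            raise SpecError("near_match_fraction must be in [0, 1]")
        if not 0.0 <= self.others_fraction <= 1.0:
            raise SpecError("others_fraction must be in [0, 1]")
        if self.branching < 1:
            raise SpecError("branching must be >= 1")
        if self.n_terminology_concepts < 1:
            raise SpecError("n_terminology_concepts must be >= 1")
        n_excl = self.n_specialty_exclusive
        if n_excl < 0:
            raise SpecError("n_specialty_exclusive must be >= 0")
        if n_excl > self.region_cardinalities["E"]:
            raise SpecError(
                "n_specialty_exclusive exceeds region E cardinality "
                f"({n_excl} > {self.region_cardinalities['E']})"
            )
        if self.region_score_sums is not None:
            for label, s in self.region_score_sums.items():
                size = self.region_cardinalities[label]
                mapped = int(round(self.region_mapped_rates.get(label, 1.0) * size))
                if mapped and not 0 < s / mapped <= 1.0:
                    raise SpecError(
                        f"region {label}: score sum {s} implies a mean "
                        f"per-concept score outside (0, 1]"
                    )

    @property
    def n_near_pairs(self) -> int:
        return int(round(self.near_match_fraction * self.region_cardinalities["G"]))


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def generate_terminology(spec: SyntheticSpec) -> TerminologyGraph:
    """Random is-a tree with reserved vertex-disjoint edges for planted
    near-match pairs, optional extra cross edges, and synonym terms.

    The first ``2 * n_near_pairs`` nodes form a caterpillar: a chain of
    "parent" nodes each carrying one pendant "child", so every reserved
    (parent, child) edge is vertex-disjoint from the others and the child
    has no other neighbour.  Remaining nodes attach to random earlier
    nodes with the configured branching preference.
    """
    spec.validate()
    rng = _rng(spec, 1)
    n_reserved = 2 * spec.n_near_pairs
    n = max(spec.n_terminology_concepts, n_reserved)
    graph = TerminologyGraph()
    ids = [f"T{idx:07d}" for idx in range(n)]
    for idx, cid in enumerate(ids):
        graph.add_concept(cid, f"node {idx:07d}")

    # caterpillar over the reserved nodes: even = parent chain, odd = pendant
    for pair in range(spec.n_near_pairs):
        parent, child = ids[2 * pair], ids[2 * pair + 1]
        graph.add_edge(child, parent)
        if pair > 0:
            graph.add_edge(ids[2 * (pair - 1)], parent)
    # attach the rest as a random tree biased to the configured branching
    start = max(n_reserved, 1)
    for idx in range(start, n):
        lo = max(0, idx - spec.branching * 4)
        parent_idx = int(rng.integers(lo, idx))
        graph.add_edge(ids[idx], ids[parent_idx])
    # optional extra cross edges among non-reserved nodes
    free = ids[n_reserved:]
    n_extra = int(spec.extra_edge_fraction * len(free))
    for _ in range(n_extra):
        a, b = rng.integers(0, len(free), size=2)
        if a != b:
            graph.add_edge(free[int(a)], free[int(b)])
    # synonym surface terms for a configurable subset
    n_syn = int(spec.synonym_fraction * n)
    for idx in range(n_syn):
        graph.add_term(f"synonym {idx:07d}", ids[idx])
    return graph


@dataclass
class GeneratedCorpora:
    """In-memory handles plus the files written by :func:`generate_corpora`."""

    spec: SyntheticSpec
    records: list[AnnotationRecord]
    region_keys: dict[str, list[tuple[str, str, str]]]  # (term, group, patient)
    terminology: TerminologyGraph
    profile: FrequencyProfile
    exclusive_concepts: list[tuple[str, str]]
    paths: dict[str, Path]


def _expand_groups(spec: SyntheticSpec, label: str, count: int, rng) -> list[str]:
    planted = (spec.region_group_counts or {}).get(label)
    if planted is not None:
        out: list[str] = []
        for group in sorted(planted):
            out.extend([group] * planted[group])
        return out
    groups = sorted(spec.semantic_group_weights)
    weights = np.array([spec.semantic_group_weights[g] for g in groups])
    weights = weights / weights.sum()
    picks = rng.choice(len(groups), size=count, p=weights)
    return [groups[i] for i in picks]


def generate_corpora(
    spec: SyntheticSpec, out_dir: str | Path
) -> GeneratedCorpora:
    """Generate annotation, metadata, terminology and background files.

    After experiencer filtering, corpus assignment and set construction,
    the region partition of the generated corpora equals
    ``spec.region_cardinalities`` exactly, with the planted per-group
    composition in the overlap regions.
    """
    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = dt.date(2016, 1, 4)

    # --- patients, dates, documents ------------------------------------
    rng_dates = _rng(spec, 2)
    patients = [f"P{idx:05d}" for idx in range(spec.n_patients)]
    n_fallback = int(spec.pdf_fallback_fraction * spec.n_patients)
    reference: dict[str, dt.date] = {}
    initial: dict[str, dt.date] = {}
    metadata_rows: list[tuple[str, str, str, dt.date]] = []
    icn_docs: dict[str, list[str]] = {}
    fcn_docs: dict[str, list[tuple[str, dt.date]]] = {}
    for idx, pid in enumerate(patients):
        ref = base + dt.timedelta(days=int(idx % 120))
        reference[pid] = ref
        initial[pid] = ref + dt.timedelta(days=7)
        omr_doc = f"{pid}-omr-001"
        if idx < n_fallback:
            metadata_rows.append((pid, omr_doc, "pdf_creation", ref))
            metadata_rows.append(
                (pid, omr_doc, "pdf_creation", ref - dt.timedelta(days=15))
            )
        else:
            metadata_rows.append((pid, omr_doc, "expert_metadata", ref))
            metadata_rows.append(
                (pid, omr_doc, "expert_metadata", ref - dt.timedelta(days=30))
            )
        n_icn = 2 if idx % 5 == 0 else 1  # some encounter days span settings
        icn_docs[pid] = [f"{pid}-icn-{j:03d}" for j in range(n_icn)]
        offsets = set(
            int(o) for o in rng_dates.choice(np.arange(1, 91), size=3, replace=False)
        )
        if idx == 0:
            offsets.add(90)  # exercise the window boundary by construction
        fcn_docs[pid] = [
            (f"{pid}-fcn-{off:03d}", initial[pid] + dt.timedelta(days=off))
            for off in sorted(offsets)
        ]

    # --- planted region concepts ---------------------------------------
    rng_groups = _rng(spec, 3)
    region_keys: dict[str, list[tuple[str, str, str]]] = {}
    cursor = 0
    for label in REGION_LABELS:
        count = spec.region_cardinalities[label]
        groups = _expand_groups(spec, label, count, rng_groups)
        keys = []
        for j in range(count):
            pid = patients[cursor % spec.n_patients]
            cursor += 1
            keys.append((f"{label.lower()} term {j:06d}", groups[j], pid))
        region_keys[label] = keys

    # --- mention records ------------------------------------------------
    rng_mention = _rng(spec, 4)
    section_names = sorted(spec.section_weights)
    section_p = np.array([spec.section_weights[s] for s in section_names])
    section_p = section_p / section_p.sum()

    _section_buf: list[int] = []

    def pick_section() -> str:
        # buffered draws: one vectorized choice() per 8192 sections
        if not _section_buf:
            _section_buf.extend(
                rng_mention.choice(len(section_names), size=8192, p=section_p).tolist()
            )
        return section_names[_section_buf.pop()]

    records: list[AnnotationRecord] = []

    def emit(pid, doc, tag, date, section, term, group, experiencer="Patient"):
        records.append(
            AnnotationRecord(
                patient_id=pid,
                document_id=doc,
                corpus_tag=tag,
                note_date=date,
                section=section,
                term=term,
                cui=None,
                semantic_group=group,
                experiencer=experiencer,
                assertion="present",
            )
        )

    for label in REGION_LABELS:
        membership = REGION_MEMBERSHIP[label]
        for term, group, pid in region_keys[label]:
            for corpus in membership:
                extra = int(rng_mention.poisson(spec.mention_extra_mean))
                if corpus == "OMR":
                    for _ in range(1 + extra):
                        emit(pid, f"{pid}-omr-001", "OMR", None, "UNKNOWN", term, group)
                elif corpus == "ICN":
                    docs = icn_docs[pid]
                    doc = docs[int(rng_mention.integers(len(docs)))]
                    for _ in range(1 + extra):
                        emit(pid, doc, "CN", initial[pid], pick_section(), term, group)
                else:  # FCN
                    docs = fcn_docs[pid]
                    doc, date = docs[int(rng_mention.integers(len(docs)))]
                    for _ in range(1 + extra):
                        emit(pid, doc, "CN", date, pick_section(), term, group)

    # --- "Others" mentions the pipeline must filter ----------------------
    rng_others = _rng(spec, 5)
    n_others = int(round(spec.others_fraction * len(records)))
    for j in range(n_others):
        pid = patients[int(rng_others.integers(spec.n_patients))]
        group = "DISO" if j % 2 else "FIND"
        if j % 2:
            doc = icn_docs[pid][0]
            emit(pid, doc, "CN", initial[pid], pick_section(),
                 f"others noise {j:06d}", group, experiencer="Others")
        else:
            emit(pid, f"{pid}-omr-001", "OMR", None, "UNKNOWN",
                 f"others noise {j:06d}", group, experiencer="Others")

    # --- prior in-house notes (dropped + logged downstream) --------------
    rng_prior = _rng(spec, 6)
    icn_by_patient: dict[str, tuple[str, str]] = {}
    for label in ("B", "E", "A", "D"):
        for term, group, pid in region_keys[label]:
            icn_by_patient.setdefault(pid, (term, group))
    n_prior = int(spec.prior_note_fraction * spec.n_patients)
    prior_patients = sorted(rng_prior.choice(spec.n_patients, size=n_prior, replace=False))
    for pidx in prior_patients:
        pid = patients[int(pidx)]
        if pid not in icn_by_patient:
            continue
        term, group = icn_by_patient[pid]
        emit(pid, f"{pid}-prior-001", "CN",
             reference[pid] - dt.timedelta(days=23), pick_section(), term, group)

    # --- terminology + near-match plants ---------------------------------
    terminology = generate_terminology(spec)
    ids = sorted(terminology.preferred_terms)
    counterpart_pool = (
        region_keys["E"] + region_keys["F"] + region_keys["D"]
    )
    n_pairs = min(spec.n_near_pairs, len(counterpart_pool))
    for pair in range(n_pairs):
        g_term = region_keys["G"][pair][0]
        cn_term = counterpart_pool[pair][0]
        parent, child = ids[2 * pair], ids[2 * pair + 1]
        terminology.add_term(cn_term, parent)
        terminology.add_term(g_term, child)

    # --- background frequency profile ------------------------------------
    rng_bg = _rng(spec, 7)
    profile = FrequencyProfile()
    denom = spec.background_denominator
    exclusive: list[tuple[str, str]] = [
        (term, group) for term, group, _pid in region_keys["E"][: spec.n_specialty_exclusive]
    ]
    exclusive_set = set(exclusive)
    for label in REGION_LABELS:
        keys = region_keys[label]
        size = len(keys)
        if size == 0:
            continue
        rate = spec.region_mapped_rates.get(label, 1.0)
        n_mapped = int(round(rate * size))
        mapped_idx = set(
            int(i) for i in rng_bg.choice(size, size=n_mapped, replace=False)
        )
        # exclusives must be mapped
        for j, (term, group, _pid) in enumerate(keys):
            if (term, group) in exclusive_set:
                mapped_idx.add(j)
        while len(mapped_idx) > n_mapped:
            # drop a non-exclusive index to keep the planted mapped count
            for j in sorted(mapped_idx, reverse=True):
                if (keys[j][0], keys[j][1]) not in exclusive_set:
                    mapped_idx.discard(j)
                    break
        mapped = sorted(mapped_idx)
        n_excl_here = sum(
            1 for j in mapped if (keys[j][0], keys[j][1]) in exclusive_set
        )
        n_free = len(mapped) - n_excl_here
        if spec.region_score_sums is not None:
            target = spec.region_score_sums.get(label, 0.0) - n_excl_here * 1.0
        else:
            target = 0.086 * n_free
        if n_free > 0:
            weights = rng_bg.uniform(0.5, 1.5, size=n_free)
            share = weights / weights.sum() * target
            counts = np.maximum(1, np.round(share * denom).astype(np.int64))
            counts = np.minimum(counts, denom)
            # nudge the largest count so the planted region score sum is
            # exact at the common denominator
            residue = int(round(target * denom)) - int(counts.sum())
            k = int(np.argmax(counts))
            counts[k] = min(denom, max(1, counts[k] + residue))
        else:
            counts = np.array([], dtype=np.int64)
        fidx = 0
        for j in mapped:
            term, group, _pid = keys[j]
            if (term, group) in exclusive_set:
                specialty = int(rng_bg.integers(50, 500))
                profile.add(term, group, specialty, specialty)
            else:
                profile.add(term, group, int(counts[fidx]), denom)
                fidx += 1

    # --- write everything -------------------------------------------------
    paths = {
        "annotations": out_dir / "annotations.tsv",
        "metadata": out_dir / "metadata.tsv",
        "terminology": out_dir / "terminology.tsv",
        "background": out_dir / "background.tsv",
        "manifest": out_dir / "manifest.json",
    }
    write_annotations(records, paths["annotations"])
    with paths["metadata"].open("w", encoding="utf-8", newline="") as fh:
        fh.write("patient_id\tdocument_id\tsource\tdate\n")
        for pid, doc, source, date in metadata_rows:
            fh.write(f"{pid}\t{doc}\t{source}\t{date.isoformat()}\n")
    save_terminology(terminology, paths["terminology"])
    profile.write(paths["background"])
    manifest = {
        "spec": dataclasses.asdict(spec),
        "n_records": len(records),
        "n_near_pairs": n_pairs,
        "exclusive_concepts": [list(pair) for pair in exclusive],
    }
    paths["manifest"].write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return GeneratedCorpora(
        spec=spec,
        records=records,
        region_keys=region_keys,
        terminology=terminology,
        profile=profile,
        exclusive_concepts=exclusive,
        paths=paths,
    )
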