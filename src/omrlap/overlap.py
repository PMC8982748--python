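"""Seven-region concept partition, intersection ratios and coverage tables.

Three corpus-level concept sets — outside medical records (OMR), initial
consultant notes (ICN) and follow-up consultant notes (FCN) — decompose
into the seven disjoint cells of their Venn diagram:

    A = OMR ∩ ICN ∩ FCN          (carried through the whole episode)
    B = (OMR ∩ ICN) − A          (used initially, dropped in follow-up)
    C = (OMR ∩ FCN) − A          (missed initially, recovered later)
    D = (ICN ∩ FCN) − A          (new in-house, persistent)
    E = ICN − (OMR ∪ FCN)        (new in-house, initial only)
    F = FCN − (OMR ∪ ICN)        (new in-house, follow-up only)
    G = OMR − (ICN ∪ FCN)        (outside-record information never used)

Two overlap statistics are computed against the combined note corpus
C_CN = ICN ∪ FCN: the exact intersection ratio r_e = |OMR ∩ CN| / |CN|
and the flexible ratio r_s = |C_SIMILAR| / |CN|, where C_SIMILAR collects,
for each OMR concept, the CN concept with the highest terminology path
similarity above a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotations import AnnotationRecord, ConceptKey, ConceptSet
from .terminology import TerminologyGraph, UNMAPPABLE

__all__ = [
    "REGION_LABELS",
    "RegionPartition",
    "MatchResult",
    "partition_regions",
    "exact_intersection_ratio",
    "best_flexible_match",
    "flexible_intersection_ratio",
    "semtype_coverage_table",
    "section_distribution",
    "percent",
    "round_half_up",
]

REGION_LABELS = ("A", "B", "C", "D", "E", "F", "G")


class UndefinedRatioError(ZeroDivisionError):
    """An intersection ratio with an empty denominator set."""


def round_half_up(value: float, places: int = 2) -> float:
    """Decimal round-half-up (the convention of the printed tables)."""
    q = Decimal(1).scaleb(-places)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, places: int = 2) -> float:
    """Exact-rational percentage rounded half-up to ``places`` decimals."""
    if denominator == 0:
        raise UndefinedRatioError("percentage with zero denominator")
    q = Decimal(1).scaleb(-places)
    return float(
        (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
            q, rounding=ROUND_HALF_UP
        )
    )


@dataclass(frozen=True)
class RegionPartition:
    """The seven disjoint region sets plus the source sets they came from."""

    regions: dict[str, frozenset[ConceptKey]]
    omr: ConceptSet
    icn: ConceptSet
    fcn: ConceptSet

    def __post_init__(self) -> None:
        union: set[ConceptKey] = set()
        total = 0
        for label in REGION_LABELS:
            members = self.regions[label]
            total += len(members)
            union |= members
        # Disjointness + coverage: the seven cells tile the three-set union.
        assert total == len(union)
        assert union == set(self.omr.members | self.icn.members | self.fcn.members)

    def __getitem__(self, label: str) -> frozenset[ConceptKey]:
        return self.regions[label]

    def cardinalities(self) -> dict[str, int]:
        return {label: len(self.regions[label]) for label in REGION_LABELS}

    @property
    def overlap(self) -> frozenset[ConceptKey]:
        """A ∪ B ∪ C: concepts shared between outside records and notes."""
        return self.regions["A"] | self.regions["B"] | self.regions["C"]

    @property
    def cn_union(self) -> frozenset[ConceptKey]:
        """ICN ∪ FCN as a plain set."""
        return frozenset(self.icn.members | self.fcn.members)

    def total_unique(self) -> int:
        return sum(len(self.regions[label]) for label in REGION_LABELS)


def partition_regions(
    omr: ConceptSet, icn: ConceptSet, fcn: ConceptSet
) -> RegionPartition:
    """Apply the seven set-algebra region definitions literally."""
    o, i, f = omr.members, icn.members, fcn.members
    a = o & i & f
    regions = {
        "A": frozenset(a),
        "B": frozenset((o & i) - a),
        "C": frozenset((o & f) - a),
        "D": frozenset((i & f) - a),
        "E": frozenset(i - (o | f)),
        "F": frozenset(f - (o | i)),
        "G": frozenset(o - (i | f)),
    }
    return RegionPartition(regions=regions, omr=omr, icn=icn, fcn=fcn)


def exact_intersection_ratio(omr: ConceptSet, cn: ConceptSet) -> float:
    """r_e = |OMR ∩ CN| / |CN|."""
    if len(cn) == 0:
        raise UndefinedRatioError(f"exact ratio undefined: {cn.label} is empty")
    return len(omr.members & cn.members) / len(cn)


@dataclass(frozen=True)
class MatchResult:
    """Best flexible match per OMR concept and the resulting C_SIMILAR."""

    matches: dict[ConceptKey, tuple[ConceptKey, float]]
    similar: frozenset[ConceptKey]
    threshold: float


def best_flexible_match(
    omr: ConceptSet,
    cn: ConceptSet,
    graph: TerminologyGraph,
    threshold: float = 0.0,
) -> MatchResult:
    """For each OMR concept, the CN concept with the highest path similarity.

    Similarity is computed between normalized terms (semantic group and
    patient id are dropped for the terminology lookup; the chosen
    candidate keeps its full key).  Identical terms count as identical
    concepts (similarity 1.0) whether or not the toy terminology maps
    them.  A match is recorded only when its similarity exceeds
    ``threshold``.  Ties are broken by preferring the OMR key itself when
    it is present in CN, then by the lexicographically smallest rendered
    CN key.  C_SIMILAR is the set of *distinct* CN concepts chosen, so the
    flexible ratio can never exceed 1.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")

    cn_by_term: dict[str, list[ConceptKey]] = {}
    for key in sorted(cn.members, key=ConceptKey.render):
        cn_by_term.setdefault(key.term, []).append(key)
    cn_terms = sorted(cn_by_term)
    cn_keys = frozenset(cn.members)

    # Distinct OMR terms share one BFS sweep each; per-key resolution
    # afterwards is dictionary work only.
    best_by_term: dict[str, tuple[float, str] | None] = {}
    for term in sorted({k.term for k in omr.members}):
        row = graph.similarity_row(term, cn_terms)
        if term in cn_by_term:
            row[term] = 1.0  # identical term == identical concept
        best_sim = UNMAPPABLE
        best_term: str | None = None
        for cand in cn_terms:
            sim = row[cand]
            if sim > best_sim:
                best_sim, best_term = sim, cand
        if best_term is None or best_sim <= threshold:
            best_by_term[term] = None
        else:
            best_by_term[term] = (best_sim, best_term)

    matches: dict[ConceptKey, tuple[ConceptKey, float]] = {}
    for key in sorted(omr.members, key=ConceptKey.render):
        hit = best_by_term[key.term]
        if hit is None:
            continue
        sim, cand_term = hit
        if sim == 1.0 and key in cn_keys:
            chosen = key
        else:
            chosen = cn_by_term[cand_term][0]  # lex-smallest rendered key
        matches[key] = (chosen, sim)

    return MatchResult(
        matches=matches,
        similar=frozenset(chosen for chosen, _sim in matches.values()),
        threshold=threshold,
    )


def flexible_intersection_ratio(match: MatchResult, cn: ConceptSet) -> float:
    """r_s = |C_SIMILAR| / |CN|."""
    if len(cn) == 0:
        raise UndefinedRatioError(f"flexible ratio undefined: {cn.label} is empty")
    return len(match.similar) / len(cn)


def semtype_coverage_table(partition: RegionPartition) -> pd.DataFrame:
    """Per-semantic-group coverage of the overlap regions A, B, C.

    One row per semantic group present in A ∪ B ∪ C, with the group's
    frequency in each region and that frequency as a percentage of the
    group's total across the three regions, plus a grand-total row.
    Rows are ordered by descending total (total row last).
    """
    counts: dict[str, dict[str, int]] = {}
    for region in ("A", "B", "C"):
        for key in partition[region]:
            counts.setdefault(key.semantic_group, {"A": 0, "B": 0, "C": 0})
            counts[key.semantic_group][region] += 1

    rows = []
    for group, c in counts.items():
        total = c["A"] + c["B"] + c["C"]
        rows.append(
            {
                "semantic_group": group,
                "A_freq": c["A"],
                "A_pct": percent(c["A"], total),
                "B_freq": c["B"],
                "B_pct": percent(c["B"], total),
                "C_freq": c["C"],
                "C_pct": percent(c["C"], total),
                "total": total,
            }
        )
    rows.sort(key=lambda r: (-r["total"], r["semantic_group"]))
    grand = {
        "A": sum(r["A_freq"] for r in rows),
        "B": sum(r["B_freq"] for r in rows),
        "C": sum(r["C_freq"] for r in rows),
    }
    grand_total = grand["A"] + grand["B"] + grand["C"]
    if grand_total:
        rows.append(
            {
                "semantic_group": "Total",
                "A_freq": grand["A"],
                "A_pct": percent(grand["A"], grand_total),
                "B_freq": grand["B"],
                "B_pct": percent(grand["B"], grand_total),
                "C_freq": grand["C"],
                "C_pct": percent(grand["C"], grand_total),
                "total": grand_total,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "semantic_group",
            "A_freq",
            "A_pct",
            "B_freq",
            "B_pct",
            "C_freq",
            "C_pct",
            "total",
        ],
    )


def section_distribution(
    records: Sequence[AnnotationRecord],
    concepts: ConceptSet | Iterable[ConceptKey],
    known_sections: Iterable[str] | None = None,
) -> dict[str, int]:
    """Distinct (concept, section) incidences for concepts in ``concepts``.

    One concept can appear in several sections of a single note
    concurrently; each distinct (concept, section) pair counts once, no
    matter how many documents repeat it.  Unknown section labels are
    folded into "UNKNOWN".
    """
    members = (
        concepts.members if isinstance(concepts, ConceptSet) else frozenset(concepts)
    )
    from .annotations import SECTIONS

    known = frozenset(known_sections) if known_sections is not None else frozenset(SECTIONS)
    seen: set[tuple[ConceptKey, str]] = set()
    counts: dict[str, int] = {}
    for r in records:
        key = r.concept_key
        if key not in members:
            continue
        section = r.section if r.section in known else "UNKNOWN"
        if (key, section) in seen:
            continue
        seen.add((key, section))
        counts[section] = counts.get(section, 0) + 1
    return counts


def brute_force_partition(
    omr: ConceptSet, icn: ConceptSet, fcn: ConceptSet
) -> dict[str, set[ConceptKey]]:
    """Per-concept membership classification; independent oracle for
    :func:`partition_regions`, intended for small corpora."""
    table = {
        (True, True, True): "A",
        (True, True, False): "B",
        (True, False, True): "C",
        (False, True, True): "D",
        (False, True, False): "E",
        (False, False, True): "F",
        (True, False, False): "G",
    }
    out: dict[str, set[ConceptKey]] = {label: set() for label in REGION_LABELS}
    for key in omr.members | icn.members | fcn.members:
        out[table[(key in omr, key in icn, key in fcn)]].add(key)
    return out
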