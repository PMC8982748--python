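"""Specialty saliency of concepts against a background note corpus.

A concept's saliency for a specialty (here: cardiovascular medicine in
the study design this package generalizes) is its mention frequency in
the specialty's notes divided by its mention frequency across all
practice settings:

    saliency(c) = freq_specialty(c) / freq_overall(c)

A score of 1 means the concept appears exclusively in the specialty; a
score near 0 means it is either ubiquitous across practices or rare in
the specialty.  Frequencies are raw mention counts aggregated over the
whole background cohort — patient identity plays no role here, so the
profile is keyed by (term, semantic group) only.

Region-level aggregation reports, per region of the overlap partition:
how many of its concepts map into the background profile (coverage), the
sum of their scores, and the average score.  The average divides by the
number of concepts with *strictly positive* scores; the variant dividing
by all mapped concepts is reported alongside.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .annotations import ConceptKey, canonical_semantic_group, normalize_term
from .overlap import percent, round_half_up

__all__ = [
    "FrequencyProfile",
    "RegionSaliency",
    "concept_saliency",
    "region_average_saliency",
    "rank_salient_concepts",
    "build_saliency_table",
]

TypeKey = tuple[str, str]  # (term, semantic_group)


@dataclass
class FrequencyProfile:
    """Mention counts per (term, semantic group): specialty vs. overall."""

    counts: dict[TypeKey, tuple[int, int]] = field(default_factory=dict)

    def add(self, term: str, semantic_group: str, specialty: int, overall: int) -> None:
        if specialty > overall:
            raise ValueError(
                f"specialty count {specialty} exceeds overall count {overall} "
                f"for {term!r}"
            )
        if specialty < 0 or overall < 0:
            raise ValueError("counts must be non-negative")
        key = (normalize_term(term), canonical_semantic_group(semantic_group))
        s0, o0 = self.counts.get(key, (0, 0))
        self.counts[key] = (s0 + specialty, o0 + overall)

    def __contains__(self, key: TypeKey) -> bool:
        return key in self.counts

    def __len__(self) -> int:
        return len(self.counts)

    @classmethod
    def read(cls, path: str | Path) -> "FrequencyProfile":
        """Read a TSV with header term, semantic_group, specialty_count,
        overall_count."""
        profile = cls()
        with Path(path).open("r", encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                profile.add(
                    row["term"],
                    row["semantic_group"],
                    int(row["specialty_count"]),
                    int(row["overall_count"]),
                )
        return profile

    def write(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["term", "semantic_group", "specialty_count", "overall_count"])
            for (term, group) in sorted(self.counts):
                s, o = self.counts[(term, group)]
                writer.writerow([term, group, s, o])


def concept_saliency(
    profile: FrequencyProfile, concept: TypeKey | ConceptKey
) -> float | None:
    """Specialty/overall frequency ratio, or None when the concept never
    occurs in the background corpus (unmapped)."""
    key = concept.type_key if isinstance(concept, ConceptKey) else concept
    entry = profile.counts.get(key)
    if entry is None:
        return None
    specialty, overall = entry
    if overall == 0:
        return None
    return specialty / overall


@dataclass(frozen=True)
class RegionSaliency:
    """Aggregated saliency statistics for one region."""

    region: str
    original_size: int
    mapped_count: int
    coverage_pct: float          # mapped / original, 2-decimal percent
    score_sum: float             # rendered at 3 decimals in reports
    average: float               # sum / #(score > 0), 3 decimals
    average_mapped_denominator: float  # sum / mapped_count variant
    no_positive_scores: bool
    top_concepts: tuple[tuple[TypeKey, float], ...]


def region_average_saliency(
    profile: FrequencyProfile,
    region_concepts: Iterable[ConceptKey],
    region: str = "",
    k: int = 5,
) -> RegionSaliency:
    """Sum/average saliency over a region's concepts.

    Each regional concept key is projected to its (term, semantic group)
    pair for the lookup; keys absent from the background profile reduce
    the coverage ratio and contribute nothing to the sum.  The average
    divides the score sum by the number of concepts with strictly
    positive scores (0, with a flag, when there are none).
    """
    keys = list(region_concepts)
    original = len(keys)
    scores: list[float] = []
    per_type: dict[TypeKey, float] = {}
    for key in keys:
        s = concept_saliency(profile, key)
        if s is None:
            continue
        scores.append(s)
        per_type[key.type_key if isinstance(key, ConceptKey) else key] = s
    mapped = len(scores)
    total = sum(scores)
    positive = sum(1 for s in scores if s > 0)
    average = total / positive if positive else 0.0
    avg_mapped = total / mapped if mapped else 0.0
    top = rank_salient_concepts(per_type, profile, k=k)
    return RegionSaliency(
        region=region,
        original_size=original,
        mapped_count=mapped,
        coverage_pct=percent(mapped, original) if original else 0.0,
        score_sum=total,
        average=round_half_up(average, 3),
        average_mapped_denominator=round_half_up(avg_mapped, 3),
        no_positive_scores=positive == 0,
        top_concepts=tuple(top),
    )


def rank_salient_concepts(
    scores: Mapping[TypeKey, float],
    profile: FrequencyProfile,
    k: int = 5,
) -> list[tuple[TypeKey, float]]:
    """Top-k concepts by score descending.

    Ties break by higher overall (all-practice) frequency, then by the
    lexicographic "term::GROUP" rendering.  ``k`` larger than the pool
    returns the full ranking; ``k = 0`` returns an empty list.
    """
    def sort_key(item: tuple[TypeKey, float]):
        (term, group), score = item
        overall = profile.counts.get((term, group), (0, 0))[1]
        return (-score, -overall, f"{term}::{group}")

    ranked = sorted(scores.items(), key=sort_key)
    return ranked[: max(k, 0)]


def build_saliency_table(
    profile: FrequencyProfile,
    regions: Mapping[str, Iterable[ConceptKey]],
    k: int = 5,
) -> dict[str, RegionSaliency]:
    """Region-by-region saliency aggregation in region-label order."""
    return {
        label: region_average_saliency(profile, concepts, region=label, k=k)
        for label, concepts in regions.items()
    }
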