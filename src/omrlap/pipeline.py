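"""End-to-end orchestration and report rendering.

``run_pipeline`` executes the full chain — experiencer filter, corpus
assignment, concept-set construction, seven-region partition, exact (and
optionally flexible) matching, semantic-group and section tables, and
region saliency — and returns a structured :class:`RunSummary`.
``render_report`` turns a summary into the fixed-order human-readable
report (percentages at 2 decimals, saliency averages at 3).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import annotations as ann
from . import corpus as corpus_mod
from .overlap import (
    REGION_LABELS,
    MatchResult,
    RegionPartition,
    best_flexible_match,
    exact_intersection_ratio,
    flexible_intersection_ratio,
    partition_regions,
    percent,
    round_half_up,
    section_distribution,
    semtype_coverage_table,
)
from .saliency import FrequencyProfile, build_saliency_table
from .terminology import load_terminology

logger = logging.getLogger("omrlap")

__all__ = ["RunConfig", "RunSummary", "StageError", "run_pipeline", "render_report"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending entity."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"[{stage}] {detail}")


@dataclass
class RunConfig:
    annotations: Path
    metadata: Path
    terminology: Path | None = None
    background: Path | None = None
    annotation_format: str = "delimited"
    threshold: float = 0.0
    window_days: int = corpus_mod.FOLLOWUP_WINDOW_DAYS
    specialty_label: str = "Cardiovascular Medicine"
    run_flexible: bool = True
    top_k: int = 5
    output_dir: Path | None = None
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self) -> None:
        self.annotations = Path(self.annotations)
        self.metadata = Path(self.metadata)
        self.terminology = Path(self.terminology) if self.terminology else None
        self.background = Path(self.background) if self.background else None
        self.output_dir = Path(self.output_dir) if self.output_dir else None
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")
        if not 0.0 <= self.threshold < 1.0:
            raise ValueError("threshold must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class RunSummary:
    corpus_sizes: dict[str, int]
    region_cardinalities: dict[str, int]
    ratios: dict[str, float]            # fractions in [0,1]
    ratios_pct: dict[str, float]        # 2-decimal rendering
    coverage_table: "object"            # pandas DataFrame
    section_counts: dict[str, int]
    saliency: dict[str, dict] = field(default_factory=dict)
    dropped: dict[str, int] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["coverage_table"] = self.coverage_table.to_dict(orient="records")
        return json.dumps(payload, indent=2, sort_keys=True)


def run_pipeline(config: RunConfig) -> RunSummary:
    """Execute filter → assign → build sets → partition → match → tables
    → saliency, with per-stage error reporting."""
    logging.basicConfig(level=config.log_level)

    # stage: read
    for label, path in (("annotations", config.annotations), ("metadata", config.metadata)):
        if not path.exists():
            raise StageError("read", f"missing {label} file: {path}")
    try:
        records = ann.read_annotations(config.annotations, config.annotation_format)
    except (ann.SchemaError, ann.ValidationError) as exc:
        raise StageError("read", str(exc)) from exc
    metadata = corpus_mod.read_metadata(config.metadata)

    # stage: experiencer filter
    kept = ann.filter_patient_experiencer(records)
    n_filtered = len(records) - len(kept)
    logger.info("experiencer filter: dropped %d of %d mentions", n_filtered, len(records))

    # stage: corpus assignment
    timelines = corpus_mod.build_timelines(metadata, kept)
    report = corpus_mod.assign_all(timelines, window_days=config.window_days)
    icn_records, fcn_records, dropped_cn = corpus_mod.split_cn_records(
        kept, report.assignments
    )
    omr_records = [r for r in kept if r.corpus_tag == "OMR"]
    logger.info(
        "corpus assignment: %d patients, %d unresolvable, %d without initial "
        "encounter, %d unassigned notes, %d patients with prior notes",
        len(report.assignments),
        len(report.unresolvable_patients),
        len(report.no_initial_encounter),
        report.unassigned_notes,
        report.patients_with_prior_notes,
    )

    # stage: concept sets
    omr = ann.build_concept_set(omr_records, "C_OMR")
    icn = ann.build_concept_set(icn_records, "C_ICN")
    fcn = ann.build_concept_set(fcn_records, "C_FCN")
    cn = (icn | fcn).relabel("C_CN")

    # stage: partition + ratios
    partition = partition_regions(omr, icn, fcn)
    cards = partition.cardinalities()
    overlap_n = len(partition.overlap)
    total_unique = partition.total_unique()
    ratios: dict[str, float] = {}
    ratios_pct: dict[str, float] = {}

    def put(name: str, num: int, den: int) -> None:
        ratios[name] = num / den if den else 0.0
        ratios_pct[name] = percent(num, den) if den else 0.0

    put("overlap_of_total_unique", overlap_n, total_unique)
    put("overlap_of_omr", overlap_n, len(omr))
    put("overlap_of_cn_union", overlap_n, len(partition.cn_union))
    put("icn_share_of_overlap", cards["A"] + cards["B"], overlap_n)
    put("fcn_share_of_overlap", cards["A"] + cards["C"], overlap_n)
    for label in REGION_LABELS[:3]:
        put(f"region_{label}_share_of_overlap", cards[label], overlap_n)
    put("exact_ratio_icn", cards["A"] + cards["B"], len(icn))
    put("exact_ratio_fcn", cards["A"] + cards["C"], len(fcn))
    put("exact_ratio_cn", overlap_n, len(cn))
    put("omr_share_of_total_unique", len(omr), total_unique)

    # stage: flexible match
    match: MatchResult | None = None
    if config.run_flexible:
        if config.terminology is None or not config.terminology.exists():
            raise StageError(
                "match", f"missing terminology file: {config.terminology}"
            )
        graph = load_terminology(config.terminology)
        match = best_flexible_match(omr, cn, graph, threshold=config.threshold)
        put("flexible_ratio_cn", len(match.similar), len(cn))

    # stage: tables
    coverage = semtype_coverage_table(partition)
    cn_all = icn_records + fcn_records
    sections = section_distribution(cn_all, partition.cn_union)

    # stage: saliency
    saliency_out: dict[str, dict] = {}
    if config.background is not None:
        if not config.background.exists():
            raise StageError("saliency", f"missing background file: {config.background}")
        profile = FrequencyProfile.read(config.background)
        table = build_saliency_table(
            profile,
            {label: partition[label] for label in REGION_LABELS},
            k=config.top_k,
        )
        for label, rs in table.items():
            saliency_out[label] = {
                "original_size": rs.original_size,
                "mapped_count": rs.mapped_count,
                "coverage_pct": rs.coverage_pct,
                "score_sum": round_half_up(rs.score_sum, 3),
                "average": rs.average,
                "average_mapped_denominator": rs.average_mapped_denominator,
                "no_positive_scores": rs.no_positive_scores,
                "top_concepts": [
                    [f"{term}::{group}", round_half_up(score, 3)]
                    for (term, group), score in rs.top_concepts
                ],
            }

    summary = RunSummary(
        corpus_sizes={
            "C_OMR": len(omr),
            "C_ICN": len(icn),
            "C_FCN": len(fcn),
            "C_CN": len(cn),
            "total_unique": total_unique,
        },
        region_cardinalities=cards,
        ratios=ratios,
        ratios_pct=ratios_pct,
        coverage_table=coverage,
        section_counts=dict(sorted(sections.items())),
        saliency=saliency_out,
        dropped={
            "experiencer_filtered": n_filtered,
            "unresolvable_patients": len(report.unresolvable_patients),
            "no_initial_encounter": len(report.no_initial_encounter),
            "unassigned_notes": report.unassigned_notes,
            "patients_with_prior_notes": report.patients_with_prior_notes,
            "dropped_cn_records": len(dropped_cn),
        },
        config={
            "threshold": config.threshold,
            "window_days": config.window_days,
            "specialty_label": config.specialty_label,
        },
    )
    if config.output_dir is not None:
        config.output_dir.mkdir(parents=True, exist_ok=True)
        (config.output_dir / "summary.json").write_text(
            summary.to_json(), encoding="utf-8"
        )
        coverage.to_csv(
            config.output_dir / "semtype_coverage.tsv", sep="\t", index=False
        )
        (config.output_dir / "report.txt").write_text(
            render_report(summary), encoding="utf-8"
        )
    return summary


def render_report(summary: RunSummary) -> str:
    """Fixed-order plain-text report; byte-identical across re-runs on
    identical inputs."""
    lines: list[str] = []
    add = lines.append
    add("== Corpus sizes ==")
    for name in ("C_OMR", "C_ICN", "C_FCN", "C_CN", "total_unique"):
        add(f"{name:>14}: {summary.corpus_sizes[name]:,}")
    add("")
    add("== Region cardinalities (Venn A..G) ==")
    for label in REGION_LABELS:
        add(f"{label:>14}: {summary.region_cardinalities[label]:,}")
    add("")
    add("== Intersection ratios ==")
    for name in sorted(summary.ratios_pct):
        add(f"{name:>28}: {summary.ratios_pct[name]:.2f}%")
    add("")
    add("== Semantic-group coverage of overlap regions A/B/C ==")
    df = summary.coverage_table
    header = f"{'group':<12}" + "".join(
        f"{c:>10}" for c in ("A", "A%", "B", "B%", "C", "C%", "total")
    )
    add(header)
    for _, row in df.iterrows():
        add(
            f"{row['semantic_group']:<12}"
            f"{row['A_freq']:>10,}{row['A_pct']:>10.2f}"
            f"{row['B_freq']:>10,}{row['B_pct']:>10.2f}"
            f"{row['C_freq']:>10,}{row['C_pct']:>10.2f}"
            f"{row['total']:>10,}"
        )
    add("")
    add("== Note-section distribution (distinct concept-section pairs) ==")
    total_sections = sum(summary.section_counts.values())
    for section, count in summary.section_counts.items():
        pct = percent(count, total_sections) if total_sections else 0.0
        add(f"{section:>40}: {count:>8,}  ({pct:.2f}%)")
    add("")
    if summary.saliency:
        add("== Region saliency vs. background corpus ==")
        add(
            f"{'region':>7}{'mapped':>10}{'coverage':>10}{'sum':>12}"
            f"{'average':>9}{'avg(mapped)':>12}"
        )
        for label in REGION_LABELS:
            rs = summary.saliency.get(label)
            if rs is None:
                continue
            flag = "  [no positive scores]" if rs["no_positive_scores"] else ""
            add(
                f"{label:>7}{rs['mapped_count']:>10,}{rs['coverage_pct']:>9.2f}%"
                f"{rs['score_sum']:>12.3f}{rs['average']:>9.3f}"
                f"{rs['average_mapped_denominator']:>12.3f}{flag}"
            )
            for rendered, score in rs["top_concepts"]:
                add(f"{'':>9}{rendered}  ({score:.3f})")
        add("")
    add("== Dropped / filtered ==")
    for name, count in sorted(summary.dropped.items()):
        add(f"{name:>28}: {count:,}")
    add("")
    return "\n".join(lines)
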