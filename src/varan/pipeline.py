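"""End-to-end orchestration: merge -> annotate -> score -> hotspot -> report.

This is the programmatic counterpart of the command-line interface: a
resolved :class:`RunConfig` names every input, and each stage function
consumes/produces the library's own types.  No stage mutates its inputs;
two runs over identical inputs produce identical outputs except for the
report timestamp, which must be supplied explicitly for archival reruns.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

from . import __version__
from .annotate import AnnotationSnapshot, annotate, load_snapshot
from .callers import (
    BasicFilterConfig,
    attach_readcounts,
    basic_filter,
    integrate,
    read_caller_vcf,
    read_readcount_tsv,
)
from .hotspots import (
    DEFAULT_MIN_DEPTH,
    CoverageTrack,
    load_sites,
    site_overview,
)
from .metrics import compute_metrics, match_calls, read_truth_set
from .reporting import (
    SiteDetail,
    build_report,
    evaluate_rules,
    load_rulebook,
)
from .ssdl import Scheme, load_scheme, score_table
from .variants import ReferenceSequence, VariantError, VariantTable, row_field

logger = logging.getLogger("varan")


@dataclass
class RunConfig:
    """Resolved inputs for one sample run; echoed into report provenance."""

    sample_id: str
    reference_fasta: str
    caller_vcfs: dict[str, str]  # caller_id -> path
    readcounts: str | None = None
    snapshot_manifest: str | None = None
    scheme_path: str | None = None
    sites_path: str | None = None
    coverage_path: str | None = None
    rulebook_path: str | None = None
    basic_filter: BasicFilterConfig = field(default_factory=BasicFilterConfig)
    overrides: dict[str, Any] = field(default_factory=dict)
    min_site_depth: int = DEFAULT_MIN_DEPTH
    timestamp: str | None = None  # fixed timestamp for reproducible reruns

    def validate(self) -> None:
        paths = [self.reference_fasta, *self.caller_vcfs.values()]
        for opt in (
            self.readcounts,
            self.snapshot_manifest,
            self.scheme_path,
            self.sites_path,
            self.coverage_path,
            self.rulebook_path,
        ):
            if opt is not None:
                paths.append(opt)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise VariantError(f"missing input file(s): {missing}")
        if not self.caller_vcfs:
            raise VariantError("at least one caller VCF is required")


def default_scheme_path() -> Path:
    """The shipped default scoring scheme (ensemble-filtering criteria:
    caller count, dbSNP membership/PM flag, COSMIC occurrence, population
    allele frequency, VAF, base quality)."""
    return Path(__file__).parent / "schemes" / "default_scheme.json"


def apply_functional_annotation(
    table: VariantTable, prefix: str = "effects"
) -> VariantTable:
    """Promote joined functional-annotation columns (``effects.gene``,
    ``effects.effect``, ``effects.region_type``) into the table's dedicated
    gene/effect/region fields."""
    out = table.copy()
    for row in out.rows:
        gene = row.annotations.get(f"{prefix}.gene", "")
        effect = row.annotations.get(f"{prefix}.effect", "")
        region = row.annotations.get(f"{prefix}.region_type", "")
        if gene:
            row.gene = gene
        if effect:
            row.effect = effect
        if region:
            row.region_type = region
    return out


def merge_stage(cfg: RunConfig, ref: ReferenceSequence) -> VariantTable:
    outputs = [
        read_caller_vcf(path, caller_id, ref)
        for caller_id, path in sorted(cfg.caller_vcfs.items())
    ]
    table = integrate(outputs, cfg.sample_id)
    logger.info("merged %d callers into %d variant rows", len(outputs), len(table))
    if cfg.readcounts:
        table = attach_readcounts(table, read_readcount_tsv(cfg.readcounts))
    table = basic_filter(table, cfg.basic_filter)
    logger.info("%d rows after basic filter", len(table))
    return table


_STAGES = ("merge", "annotate", "score", "hotspot", "report")


def run_report_pipeline(cfg: RunConfig, through: str = "report") -> dict[str, Any]:
    """Run merge -> annotate -> score -> hotspot -> rules -> report.

    ``through`` stops the pipeline after an earlier stage (e.g. "merge").
    Returns a dict with every intermediate product plus the final report
    document (None when not reached), so callers (CLI, tests, evaluation
    scripts) can inspect any stage.
    """
    if through not in _STAGES:
        raise VariantError(f"unknown stage {through!r}; use one of {_STAGES}")
    depth = _STAGES.index(through)
    cfg.validate()
    ref = ReferenceSequence.from_fasta(cfg.reference_fasta)
    table = merge_stage(cfg, ref)

    snapshot = AnnotationSnapshot([])
    scheme: Scheme | None = None
    if depth >= 1 and cfg.snapshot_manifest:
        snapshot = load_snapshot(cfg.snapshot_manifest, ref)
        table = annotate(table, snapshot)
        table = apply_functional_annotation(table)

    if depth >= 2:
        scheme_path = cfg.scheme_path or str(default_scheme_path())
        scheme = load_scheme(scheme_path)
        table = score_table(scheme, table, cfg.overrides or None)

    overview = []
    recommendations = []
    sites = []
    registry_version = "none"
    if depth >= 3 and cfg.sites_path:
        raw = json.loads(Path(cfg.sites_path).read_text())
        if isinstance(raw, dict):
            registry_version = str(raw.get("version", "unversioned"))
        sites = load_sites(cfg.sites_path, ref)
        if cfg.coverage_path:
            cov = CoverageTrack.from_bedgraph(cfg.coverage_path)
        elif cfg.readcounts:
            cov = CoverageTrack.from_readcounts(read_readcount_tsv(cfg.readcounts))
        else:
            cov = CoverageTrack()
        overview = site_overview(sites, table, cov, cfg.min_site_depth)
        if cfg.rulebook_path:
            rulebook = load_rulebook(cfg.rulebook_path, sites)
            recommendations = evaluate_rules(rulebook, overview)

    result: dict[str, Any] = {
        "reference": ref,
        "table": table,
        "scheme": scheme,
        "sites": sites,
        "overview": overview,
        "recommendations": recommendations,
        "report": None,
    }
    if depth < 4:
        return result

    by_key = {r.key: r for r in table.rows}
    details = []
    for site, status in zip(sites, overview):
        supporting = []
        for key in status.supporting_variants:
            row = by_key[key]
            supporting.append(
                {
                    "key": key,
                    "gene": row.gene,
                    "effect": row.effect,
                    "vaf": round(row.vaf, 4),
                    "depth": row.depth,
                    "caller_count": row.caller_count,
                }
            )
        details.append(
            SiteDetail(
                site_id=site.site_id,
                gene=site.gene,
                label=site.label,
                supporting_variants=supporting,
                min_depth_observed=status.min_depth_observed,
                fraction_bases_covered=round(status.fraction_bases_covered, 6),
                notes=site.notes,
            )
        )

    timestamp = cfg.timestamp or datetime.datetime.now(datetime.timezone.utc).isoformat()
    provenance = {
        "pipeline_version": __version__,
        "scheme": f"{scheme.name} {scheme.version}",
        "threshold_overrides": json.dumps(cfg.overrides, sort_keys=True),
        "annotation_snapshot_id": snapshot.snapshot_id,
        "site_registry_version": registry_version,
        "timestamp": timestamp,
    }
    result["report"] = build_report(
        sample={"sample_id": cfg.sample_id},
        overview=overview,
        recommendations=recommendations,
        provenance=provenance,
        details=details,
    )
    return result


def evaluate_against_truth(
    cfg: RunConfig,
    truth_path: str,
    region: Sequence[tuple[str, int, int]] | None = None,
    passing_only: bool = True,
):
    """Run the pipeline and score its pass-classified calls against a
    truth set; returns (ConfusionCounts, MetricsResult)."""
    result = run_report_pipeline(cfg)
    table: VariantTable = result["table"]
    if passing_only:
        kept = [r.copy() for r in table.rows if r.classification == "pass"]
        table = VariantTable(table.sample_id, kept, list(table.column_registry))
    truth = read_truth_set(truth_path, result["reference"])
    counts = match_calls(table, truth, region=region)
    return counts, compute_metrics(counts)
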