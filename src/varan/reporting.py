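"""Rule-based diagnostic recommendations and the clinical report document.

Rules are boolean expressions over site states via ``state(site_id)``,
using the same sandboxed grammar as scheme conditions.  State logic is
three-valued: an ``INSUFFICIENT`` site satisfies neither a ``MUTATED`` nor
a ``WILDTYPE`` equality test, so a recommendation that depends on safe
exclusion of a mutation cannot fire off an under-covered region.

The report is structured coarse to fine: sample metadata, the color-coded
site overview, fired recommendations, then per-site detail blocks.  Full
provenance (pipeline version, scheme, threshold overrides, annotation
snapshot, site registry version, timestamp) is mandatory; rendering the
same document twice is byte-identical except for the timestamp.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

from .hotspots import STATE_COLORS, STATES, MutationSite, SiteStatus
from .ssdl import CompiledExpression, ExpressionError, compile_expression
from .variants import VariantError

PROVENANCE_FIELDS = (
    "pipeline_version",
    "scheme",
    "threshold_overrides",
    "annotation_snapshot_id",
    "site_registry_version",
    "timestamp",
)


class RulebookError(ValueError):
    """Invalid rulebook document (bad expression or unknown site)."""


@dataclass
class DiagnosticRule:
    rule_id: str
    condition: CompiledExpression
    recommendation_text: str
    references: list[str] = field(default_factory=list)


def parse_rulebook(
    document: str | Sequence[Mapping[str, Any]],
    sites: Sequence[MutationSite],
) -> list[DiagnosticRule]:
    """Parse and validate rules; every referenced site must exist."""
    if isinstance(document, str):
        data = json.loads(document)
    else:
        data = list(document)
    if isinstance(data, dict):
        data = data["rules"]
    known = {s.site_id for s in sites}
    rules = []
    for i, rec in enumerate(data):
        path = f"$.rules[{i}]"
        try:
            condition = compile_expression(rec["condition"], allow_state=True)
        except ExpressionError as exc:
            raise RulebookError(f"{path}.condition: {exc}") from exc
        unknown = condition.sites - known
        if unknown:
            raise RulebookError(
                f"{path}: rule {rec.get('rule_id')!r} references unknown site(s) "
                f"{sorted(unknown)}"
            )
        rules.append(
            DiagnosticRule(
                rule_id=str(rec["rule_id"]),
                condition=condition,
                recommendation_text=str(rec.get("recommendation_text", "")),
                references=[str(r) for r in rec.get("references", [])],
            )
        )
    return rules


def load_rulebook(path: str, sites: Sequence[MutationSite]) -> list[DiagnosticRule]:
    return parse_rulebook(Path(path).read_text(), sites)


def evaluate_rules(
    rulebook: Sequence[DiagnosticRule], overview: Sequence[SiteStatus]
) -> list[dict[str, Any]]:
    """Fired recommendations, in rulebook order.

    ``state(site_id)`` returns the literal three-valued state string; a
    site absent from the overview evaluates to the empty string, which
    matches no state.
    """
    states = {s.site_id: s.state for s in overview}
    fired = []
    for rule in rulebook:
        if rule.condition.evaluate(lambda _c: "", {}, lambda sid: states.get(sid, "")):
            fired.append(
                {
                    "rule_id": rule.rule_id,
                    "recommendation_text": rule.recommendation_text,
                    "references": list(rule.references),
                }
            )
    return fired


# ---------------------------------------------------------------------------
# report document
# ---------------------------------------------------------------------------


@dataclass
class SiteDetail:
    """Fine-grained per-site block: supporting variants + coverage summary."""

    site_id: str
    gene: str
    label: str
    supporting_variants: list[dict[str, Any]] = field(default_factory=list)
    min_depth_observed: int = 0
    fraction_bases_covered: float = 0.0
    notes: str = ""


@dataclass
class ReportDocument:
    sample: dict[str, Any]
    overview: list[dict[str, Any]]
    recommendations: list[dict[str, Any]]
    details: list[SiteDetail]
    provenance: dict[str, str]
    assessment_free_text: str = ""


def build_report(
    sample: Mapping[str, Any],
    overview: Sequence[SiteStatus],
    recommendations: Sequence[Mapping[str, Any]],
    provenance: Mapping[str, str],
    details: Sequence[SiteDetail] = (),
    assessment_free_text: str = "",
) -> ReportDocument:
    """Assemble a report; incomplete provenance is an error, because a
    report that cannot be reproduced is not a clinical document."""
    missing = [
        f
        for f in PROVENANCE_FIELDS
        if f not in provenance or str(provenance[f]) == ""
    ]
    if missing:
        raise VariantError(f"incomplete report provenance; missing {missing}")
    return ReportDocument(
        sample=dict(sample),
        overview=[
            {
                "site_id": s.site_id,
                "state": s.state,
                "color": s.color,
                "supporting_variants": list(s.supporting_variants),
                "min_depth_observed": s.min_depth_observed,
                "fraction_bases_covered": round(s.fraction_bases_covered, 6),
            }
            for s in overview
        ],
        recommendations=[dict(r) for r in recommendations],
        details=list(details),
        provenance={f: str(provenance[f]) for f in PROVENANCE_FIELDS},
        assessment_free_text=assessment_free_text,
    )


def report_to_dict(doc: ReportDocument) -> dict[str, Any]:
    return asdict(doc)


def report_from_json(text: str) -> ReportDocument:
    data = json.loads(text)
    data["details"] = [SiteDetail(**d) for d in data.get("details", [])]
    return ReportDocument(**data)


def render_report(doc: ReportDocument, format: str = "json") -> str:
    """Render to ``json`` (lossless, archival) or ``markdown`` (human view)."""
    if format == "json":
        return json.dumps(report_to_dict(doc), indent=2, sort_keys=True) + "\n"
    if format == "markdown":
        return _render_markdown(doc)
    raise VariantError(f"unknown report format {format!r}; use 'json' or 'markdown'")


def _render_markdown(doc: ReportDocument) -> str:
    lines = ["# Clinical variant report", ""]
    lines.append("## Sample")
    for k in sorted(doc.sample):
        lines.append(f"- {k}: {doc.sample[k]}")
    lines += ["", "## Mutation site overview", ""]
    for s in doc.overview:
        support = (
            f" — supporting: {', '.join(s['supporting_variants'])}"
            if s["supporting_variants"]
            else ""
        )
        lines.append(
            f"- [{s['color'].upper()}] {s['site_id']}: {s['state']} "
            f"(min depth {s['min_depth_observed']}, "
            f"{100 * s['fraction_bases_covered']:.1f}% covered){support}"
        )
    lines += ["", "## Diagnostic recommendations", ""]
    if doc.recommendations:
        for r in doc.recommendations:
            refs = f" [{'; '.join(r['references'])}]" if r.get("references") else ""
            lines.append(f"- ({r['rule_id']}) {r['recommendation_text']}{refs}")
    else:
        lines.append("- none")
    if doc.assessment_free_text:
        lines += ["", "## Assessment", "", doc.assessment_free_text]
    if doc.details:
        lines += ["", "## Site details", ""]
        for d in doc.details:
            lines.append(f"### {d.label} ({d.gene})")
            lines.append(
                f"- coverage: min depth {d.min_depth_observed}, "
                f"{100 * d.fraction_bases_covered:.1f}% of bases covered"
            )
            if d.supporting_variants:
                for v in d.supporting_variants:
                    desc = ", ".join(f"{k}={v[k]}" for k in sorted(v))
                    lines.append(f"- variant: {desc}")
            else:
                lines.append("- no supporting variants")
            if d.notes:
                lines.append(f"- notes: {d.notes}")
            lines.append("")
    lines += ["", "## Provenance", ""]
    for f in PROVENANCE_FIELDS:
        lines.append(f"- {f}: {doc.provenance[f]}")
    return "\n".join(lines) + "\n"
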