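"""Driver-mutation site registry and three-state coverage classification.

Each curated site is a set of genomic ranges (1 bp up to a whole exon) with
optional restrictions on mutation type.  A site is:

* ``MUTATED`` (red)       — a relevant variant overlaps it: right type,
  non-synonymous, not annotated benign, and classified ``pass`` by the
  scoring scheme;
* ``WILDTYPE`` (green)    — no relevant variant AND every base of every
  range reaches the minimum depth, so absence of a mutation is a safe call;
* ``INSUFFICIENT`` (yellow) — no relevant variant but at least one base is
  under-covered: absence cannot be safely claimed.

A mutated call never depends on coverage; wild-type exclusion always does.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .variants import (
    DEL,
    INS,
    ReferenceSequence,
    Variant,
    VariantError,
    VariantRow,
    VariantTable,
    canonical_chrom,
)

MUTATED = "MUTATED"
INSUFFICIENT = "INSUFFICIENT"
WILDTYPE = "WILDTYPE"
STATES = (MUTATED, INSUFFICIENT, WILDTYPE)
STATE_COLORS = {MUTATED: "red", INSUFFICIENT: "yellow", WILDTYPE: "green"}

#: default minimum per-base depth for wild-type exclusion
DEFAULT_MIN_DEPTH = 100

_TYPE_CHOICES = {"SNV", "INS", "DEL", "MNV", "frameshift_only", "any"}


@dataclass
class MutationSite:
    """A curated hotspot: named ranges plus mutation-type restrictions."""

    site_id: str
    gene: str
    label: str
    ranges: list[tuple[str, int, int]]  # 1-based inclusive
    type_restriction: frozenset[str] = frozenset({"any"})
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.ranges:
            raise VariantError(f"site {self.site_id!r}: needs at least one range")
        clean = []
        for chrom, start, end in self.ranges:
            if start > end or start < 1:
                raise VariantError(
                    f"site {self.site_id!r}: empty range {chrom}:{start}-{end}"
                )
            clean.append((canonical_chrom(chrom), int(start), int(end)))
        self.ranges = clean
        self.type_restriction = frozenset(self.type_restriction) or frozenset({"any"})
        bad = self.type_restriction - _TYPE_CHOICES
        if bad:
            raise VariantError(f"site {self.site_id!r}: unknown type restriction {sorted(bad)}")

    def positions(self) -> Iterable[tuple[str, int]]:
        for chrom, start, end in self.ranges:
            for pos in range(start, end + 1):
                yield chrom, pos


def load_sites(path: str, ref: ReferenceSequence | None = None) -> list[MutationSite]:
    """Load a site registry (JSON; ranges are BED-style 0-based half-open
    triples, converted to 1-based inclusive here)."""
    data = json.loads(Path(path).read_text())
    if isinstance(data, dict):
        data = data["sites"]
    sites = []
    for rec in data:
        ranges = []
        for chrom, start0, end in rec["ranges"]:
            if start0 >= end:
                raise VariantError(
                    f"site {rec.get('site_id')!r}: BED range {chrom}:{start0}-{end} is empty"
                )
            if ref is not None:
                chrom_c = canonical_chrom(chrom)
                if chrom_c not in ref.contigs:
                    raise VariantError(
                        f"site {rec.get('site_id')!r}: unknown contig {chrom!r}"
                    )
            ranges.append((chrom, int(start0) + 1, int(end)))
        sites.append(
            MutationSite(
                site_id=str(rec["site_id"]),
                gene=str(rec.get("gene", "")),
                label=str(rec.get("label", rec["site_id"])),
                ranges=ranges,
                type_restriction=frozenset(rec.get("type_restriction", ["any"])),
                notes=str(rec.get("notes", "")),
            )
        )
    return sites


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------


class CoverageTrack:
    """Per-base read depth; positions outside any provided interval are 0."""

    def __init__(self, depths: Mapping[tuple[str, int], int] | None = None):
        self._depths: dict[tuple[str, int], int] = {}
        for (chrom, pos), d in (depths or {}).items():
            if d < 0:
                raise VariantError(f"negative depth at {chrom}:{pos}")
            self._depths[(canonical_chrom(chrom), pos)] = int(d)

    def depth(self, chrom: str, pos: int) -> int:
        return self._depths.get((canonical_chrom(chrom), pos), 0)

    @classmethod
    def from_bedgraph(cls, path: str) -> "CoverageTrack":
        """BEDGRAPH-style TSV: chrom, start (0-based), end, depth."""
        depths: dict[tuple[str, int], int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                chrom, start0, end, depth = line.split("\t")[:4]
                for pos in range(int(start0) + 1, int(end) + 1):
                    depths[(chrom, pos)] = int(float(depth))
        return cls(depths)

    @classmethod
    def from_readcounts(cls, records) -> "CoverageTrack":
        return cls({(r.chrom, r.pos): r.depth for r in records})


# ---------------------------------------------------------------------------
# relevance and classification
# ---------------------------------------------------------------------------


def _overlap_positions(v: Variant) -> list[tuple[str, int]]:
    """Positions at which a variant counts as hitting a range.

    A deletion hits where a deleted base lies; an insertion hits at its
    anchor base or the base after (insertions in repeats have ambiguous
    placement); substitutions hit every changed reference base.
    """
    t = v.vtype
    if t == INS:
        return [(v.chrom, v.pos), (v.chrom, v.pos + 1)]
    if t == DEL:
        anchored = v.ref[0] == v.alt[0]
        start = v.pos + 1 if anchored else v.pos
        return [(v.chrom, p) for p in range(start, v.pos + len(v.ref))]
    return [(v.chrom, p) for p in range(v.pos, v.end + 1)]


def _in_ranges(v: Variant, ranges: Sequence[tuple[str, int, int]]) -> bool:
    for chrom, pos in _overlap_positions(v):
        for rchrom, start, end in ranges:
            if chrom == rchrom and start <= pos <= end:
                return True
    return False


def _is_synonymous(effect: str) -> bool:
    e = effect.lower().replace("-", "").replace("_", "")
    return "synonymous" in e and "nonsynonymous" not in e


def _is_benign(row: VariantRow) -> bool:
    """A variant is benign iff some clinical-significance column says so;
    absence of such a column counts as not-benign (conservative toward
    reporting)."""
    for col, value in row.annotations.items():
        stem = col.rsplit(".", 1)[-1].lower()
        if stem in ("clinsig", "clnsig", "clinical_significance", "significance"):
            if "benign" in value.lower():
                return True
    return False


def _type_allowed(row: VariantRow, restriction: frozenset[str]) -> bool:
    if "any" in restriction:
        return True
    if row.variant.vtype in restriction:
        return True
    if "frameshift_only" in restriction and "frameshift" in row.effect.lower():
        return True
    return False


def is_relevant(row: VariantRow, site: MutationSite) -> bool:
    """True iff the row is a reportable driver mutation for this site:
    overlaps a range, satisfies the type restriction, is non-synonymous,
    not annotated benign, and passed A/P classification."""
    return (
        _in_ranges(row.variant, site.ranges)
        and _type_allowed(row, site.type_restriction)
        and not _is_synonymous(row.effect)
        and not _is_benign(row)
        and row.classification == "pass"
    )


@dataclass
class SiteStatus:
    site_id: str
    state: str
    supporting_variants: list[str] = field(default_factory=list)
    min_depth_observed: int = 0
    fraction_bases_covered: float = 0.0

    @property
    def color(self) -> str:
        return STATE_COLORS[self.state]


def classify_site(
    site: MutationSite,
    table: VariantTable,
    cov: CoverageTrack,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> SiteStatus:
    """Three-state classification; a found mutation overrides coverage."""
    if min_depth < 1:
        raise VariantError("min_depth must be >= 1")
    supporting = [r.key for r in table.rows if is_relevant(r, site)]
    positions = list(site.positions())
    depths = [cov.depth(c, p) for c, p in positions]
    covered = sum(1 for d in depths if d >= min_depth)
    fraction = covered / len(depths)
    min_observed = min(depths)
    if supporting:
        state = MUTATED
    elif fraction == 1.0:
        state = WILDTYPE
    else:
        state = INSUFFICIENT
    return SiteStatus(
        site_id=site.site_id,
        state=state,
        supporting_variants=supporting,
        min_depth_observed=min_observed,
        fraction_bases_covered=fraction,
    )


def site_overview(
    sites: Sequence[MutationSite],
    table: VariantTable,
    cov: CoverageTrack,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> list[SiteStatus]:
    """One status per site in stable registry order."""
    return [classify_site(s, table, cov, min_depth) for s in sites]


def state_counts(overview: Sequence[SiteStatus]) -> dict[str, int]:
    counts = {s: 0 for s in STATES}
    for status in overview:
        counts[status.state] += 1
    return counts
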