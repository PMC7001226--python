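"""Multi-caller VCF ingestion, merging, readcount metrics, basic filter.

Each caller's VCF is read, multiallelic records are split, every allele is
normalized, and the per-caller lists are merged into one table keyed by the
canonical variant representation, so that equivalent emissions from
different callers land on the same row.  Quality metrics (VAF, depth, mean
base quality) come from one shared per-base readcount table rather than
from the callers' own AD/AF fields, giving all callers a common
denominator.  A configurable basic quality filter removes obvious
low-quality rows before scoring; anything subtler is the scoring scheme's
job, so caller FILTER status is kept as an opaque column, not acted on.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

from .variants import (
    DEL,
    INS,
    MNV,
    SNV,
    ReferenceSequence,
    Variant,
    VariantError,
    VariantRow,
    VariantTable,
    canonical_chrom,
    decompose_mnv,
    normalize_variant,
    split_multiallelic,
    variant_key,
)

logger = logging.getLogger("varan")

_SYMBOLIC = ("<", ">", "[", "]", ".")


@dataclass
class CallerOutput:
    """Normalized, deduplicated variants from one calling tool."""

    caller_id: str
    variants: list[Variant] = field(default_factory=list)
    #: native quality fields per variant key, kept verbatim as strings
    native: dict[str, dict[str, str]] = field(default_factory=dict)


def _is_supported_allele(allele: str | None) -> bool:
    if not allele or allele == "*":
        return False
    if any(ch in allele for ch in _SYMBOLIC):
        return False
    return set(allele.upper()) <= set("ACGT")


def read_caller_vcf(
    path: str,
    caller_id: str,
    ref: ReferenceSequence,
    decompose_mnvs: bool = False,
) -> CallerOutput:
    """Read one caller's VCF (plain or gzip), normalize every emission.

    Records failing FILTER are retained but flagged — the native FILTER
    string is exposed as column ``<caller_id>.FILTER`` for the scoring
    scheme.  Symbolic alleles, spanning-deletion ``*`` alleles and alleles
    containing N are dropped with a logged warning: the tool targets SNVs
    and small indels.  Multi-nucleotide substitutions are kept whole unless
    ``decompose_mnvs`` asks for their component SNVs.
    """
    out = CallerOutput(caller_id=caller_id)
    seen: set[str] = set()
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VariantError(f"cannot parse VCF {path}: {exc}") from exc
    with vcf:
        for lineno, rec in enumerate(vcf.fetch() if vcf.index else vcf, start=1):
            chrom = canonical_chrom(rec.chrom)
            if chrom not in ref.contigs:
                raise VariantError(
                    f"{path}: record {lineno}: contig {rec.chrom!r} absent from reference"
                )
            alts = rec.alts or ()
            kept = [a for a in alts if _is_supported_allele(a)]
            dropped = [a for a in alts if not _is_supported_allele(a)]
            if dropped:
                logger.warning(
                    "%s: record %s at %s:%s: dropping unsupported allele(s) %s",
                    path, lineno, chrom, rec.pos, dropped,
                )
            if not kept or not _is_supported_allele(rec.ref):
                continue
            filter_status = ";".join(rec.filter.keys()) or "."
            qual = "" if rec.qual is None else f"{rec.qual:g}"
            try:
                split = split_multiallelic(chrom, rec.pos, rec.ref, kept)
            except VariantError as exc:
                raise VariantError(f"{path}: record {lineno}: {exc}") from exc
            if decompose_mnvs:
                split = [piece for s in split for piece in decompose_mnv(s)]
            for raw in split:
                try:
                    v = normalize_variant(raw, ref)
                except VariantError as exc:
                    raise VariantError(f"{path}: record {lineno}: {exc}") from exc
                key = variant_key(v)
                if key in seen:
                    continue
                seen.add(key)
                out.variants.append(v)
                out.native[key] = {
                    f"{caller_id}.FILTER": filter_status,
                    f"{caller_id}.QUAL": qual,
                }
    return out


def integrate(outputs: Sequence[CallerOutput], sample_id: str) -> VariantTable:
    """Merge caller outputs into one table, one row per unique key.

    The result is independent of the order in which outputs are supplied;
    ``caller_flags[c]`` is true iff caller ``c`` emitted the variant.
    """
    if not outputs:
        raise VariantError("integrate needs at least one caller output")
    ids = [o.caller_id for o in outputs]
    if len(set(ids)) != len(ids):
        raise VariantError(f"duplicate caller ids in {ids}")

    by_key: dict[str, VariantRow] = {}
    native_cols: set[str] = set()
    for output in sorted(outputs, key=lambda o: o.caller_id):
        for v in output.variants:
            key = variant_key(v)
            row = by_key.get(key)
            if row is None:
                row = VariantRow(
                    variant=v,
                    caller_flags={c: False for c in ids},
                )
                by_key[key] = row
            row.caller_flags[output.caller_id] = True
            fields = output.native.get(key, {})
            row.annotations.update(fields)
            native_cols.update(fields)

    table = VariantTable(sample_id, list(by_key.values()))
    table.register_columns(sorted(native_cols))
    return table


# ---------------------------------------------------------------------------
# readcount table
# ---------------------------------------------------------------------------


@dataclass
class ReadcountRecord:
    """Per-base allele counts and mean base qualities at one position."""

    chrom: str
    pos: int
    ref_base: str
    depth: int
    allele_counts: dict[str, int] = field(default_factory=dict)
    mean_base_quality: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chrom = canonical_chrom(self.chrom)
        if self.depth < 0:
            raise VariantError(f"negative depth at {self.chrom}:{self.pos}")
        if sum(self.allele_counts.values()) > self.depth:
            raise VariantError(
                f"allele counts exceed depth at {self.chrom}:{self.pos}"
            )


def read_readcount_tsv(path: str) -> list[ReadcountRecord]:
    """Read a readcount table: chrom, pos, ref, depth, then
    ``allele:count:mean_bq`` triplets (one per column)."""
    records = []
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise VariantError(f"{path}:{lineno}: expected >= 4 columns")
            chrom, pos, ref_base, depth = parts[:4]
            counts: dict[str, int] = {}
            quals: dict[str, float] = {}
            for triplet in parts[4:]:
                if not triplet:
                    continue
                allele, count, bq = triplet.rsplit(":", 2)
                counts[allele] = int(count)
                quals[allele] = float(bq)
            records.append(
                ReadcountRecord(chrom, int(pos), ref_base, int(depth), counts, quals)
            )
    return records


def supporting_allele_key(v: Variant) -> str:
    """Readcount-table key for the allele supporting a variant.

    SNV/MNV use the alternate bases; insertions use ``+inserted`` and
    deletions ``-deleted`` (the convention of per-base readcount tools).
    """
    t = v.vtype
    if t == INS:
        return "+" + v.alt[len(v.ref):] if v.alt.startswith(v.ref) else "+" + v.alt[1:]
    if t == DEL:
        return "-" + v.ref[len(v.alt):] if v.ref.startswith(v.alt) else "-" + v.ref[1:]
    return v.alt


def attach_readcounts(
    table: VariantTable, records: Iterable[ReadcountRecord]
) -> VariantTable:
    """Fill VAF, depth and mean base quality from the readcount table.

    VAF is supporting-allele count / depth at the variant's anchor position
    (0 at depth 0).  Rows without a readcount record get zeros plus a
    ``no_readcount`` flag so downstream schemes can treat them explicitly.
    Missing data is represented, never fatal.
    """
    index: dict[tuple[str, int], ReadcountRecord] = {
        (r.chrom, r.pos): r for r in records
    }
    out = table.copy()
    out.register_columns(["no_readcount"])
    for row in out.rows:
        rec = index.get((row.variant.chrom, row.variant.pos))
        if rec is None:
            row.depth = 0
            row.vaf = 0.0
            row.mean_base_quality = 0.0
            row.annotations["no_readcount"] = "1"
            continue
        allele = supporting_allele_key(row.variant)
        count = rec.allele_counts.get(allele, 0)
        row.depth = rec.depth
        row.vaf = count / rec.depth if rec.depth > 0 else 0.0
        row.mean_base_quality = rec.mean_base_quality.get(allele, 0.0)
        row.annotations["no_readcount"] = ""
    return out


# ---------------------------------------------------------------------------
# basic pre-scoring quality filter
# ---------------------------------------------------------------------------


@dataclass
class BasicFilterConfig:
    """Coarse quality gate applied before scoring.

    Defaults are conservative and fully configurable: 20x depth, 1% VAF,
    Q15 mean base quality, at least one caller.
    """

    min_depth: int = 20
    min_vaf: float = 0.01
    min_base_quality: float = 15.0
    min_caller_count: int = 1

    def __post_init__(self) -> None:
        if min(self.min_depth, self.min_vaf, self.min_base_quality, self.min_caller_count) < 0:
            raise VariantError("basic filter thresholds must be non-negative")
        if self.min_vaf > 1:
            raise VariantError("min_vaf must be <= 1")


def basic_filter(table: VariantTable, cfg: BasicFilterConfig) -> VariantTable:
    """Keep rows meeting every minimum; log each removal with its reason."""
    kept = []
    for row in table.rows:
        failed = None
        if row.depth < cfg.min_depth:
            failed = f"depth {row.depth} < {cfg.min_depth}"
        elif row.vaf < cfg.min_vaf:
            failed = f"vaf {row.vaf:.4f} < {cfg.min_vaf}"
        elif row.mean_base_quality < cfg.min_base_quality:
            failed = f"mean_base_quality {row.mean_base_quality:.1f} < {cfg.min_base_quality}"
        elif row.caller_count < cfg.min_caller_count:
            failed = f"caller_count {row.caller_count} < {cfg.min_caller_count}"
        if failed:
            logger.info("basic_filter removed %s: %s", row.key, failed)
        else:
            kept.append(row.copy())
    return VariantTable(table.sample_id, kept, list(table.column_registry))


# ---------------------------------------------------------------------------
# merged-table VCF export
# ---------------------------------------------------------------------------


def write_table_vcf(table: VariantTable, path: str, ref: ReferenceSequence) -> None:
    """Export the merged table as a one-sample VCF with INFO keys CALLERS,
    CALLER_COUNT, VAF, DP and MBQ."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=varan merge ({table.sample_id})",
    ]
    for contig in sorted(ref.contigs, key=lambda c: (c != "chrM", c)):
        lines.append(f"##contig=<ID={contig},length={len(ref.contigs[contig])}>")
    lines += [
        '##INFO=<ID=CALLERS,Number=.,Type=String,Description="Callers that emitted this variant">',
        '##INFO=<ID=CALLER_COUNT,Number=1,Type=Integer,Description="Number of callers">',
        '##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency from readcounts">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth from readcounts">',
        '##INFO=<ID=MBQ,Number=1,Type=Float,Description="Mean base quality of supporting reads">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for row in table.rows:
        v = row.variant
        callers = ",".join(sorted(c for c, on in row.caller_flags.items() if on)) or "."
        info = (
            f"CALLERS={callers};CALLER_COUNT={row.caller_count};"
            f"VAF={row.vaf:.6g};DP={row.depth};MBQ={row.mean_base_quality:.6g}"
        )
        lines.append(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t{info}")
    Path(path).write_text("\n".join(lines) + "\n")
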