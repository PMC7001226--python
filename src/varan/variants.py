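"""Canonical variant representation and the filterable variant table.

A variant is stored in exactly one representation: parsimonious (no shared
prefix/suffix between REF and ALT beyond the single anchor base required for
indels) and maximally left-aligned against the reference sequence.  All
merging, annotation and truth-set matching in this package joins on the key
of that canonical form, so equivalent descriptions emitted by different
callers or databases collide on one row.

Coordinates are 1-based inclusive throughout (VCF convention); BED-style
0-based half-open inputs are converted at the parser boundary, never here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pyfaidx import Fasta

logger = logging.getLogger("varan")

VALID_BASES = frozenset("ACGTN")
SNV = "SNV"
INS = "INS"
DEL = "DEL"
MNV = "MNV"
VARIANT_TYPES = (SNV, INS, DEL, MNV)

REGION_TYPES = ("exon", "intron", "hotspot", "other")

# classifications a row can carry after scoring
PASS = "pass"
ARTIFACT = "artifact"
POLYMORPHISM = "polymorphism"
ARTIFACT_AND_POLYMORPHISM = "artifact_and_polymorphism"
UNSCORED = "unscored"


class VariantError(ValueError):
    """Invalid variant data (reference mismatch, bad allele, bad contig)."""


# ---------------------------------------------------------------------------
# contig naming and ordering
# ---------------------------------------------------------------------------

_CHR_RE = re.compile(r"^(chr)?(.+)$", re.IGNORECASE)


def canonical_chrom(name: str) -> str:
    """Normalize a contig name to the 'chr'-prefixed dialect ('MT' -> 'chrM')."""
    m = _CHR_RE.match(name.strip())
    body = m.group(2)
    if body.upper() in ("M", "MT"):
        body = "M"
    return "chr" + body


def contig_sort_key(chrom: str) -> tuple:
    """Natural order chr1..chr22, chrX, chrY, chrM, then lexicographic."""
    body = canonical_chrom(chrom)[3:]
    if body.isdigit():
        return (0, int(body), "")
    special = {"X": 23, "Y": 24, "M": 25}
    if body.upper() in special:
        return (0, special[body.upper()], "")
    return (1, 0, body)


# ---------------------------------------------------------------------------
# reference sequence
# ---------------------------------------------------------------------------


@dataclass
class ReferenceSequence:
    """Uppercase DNA per contig with 1-based inclusive coordinate access."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        clean: dict[str, str] = {}
        for name, seq in self.contigs.items():
            seq = seq.upper()
            bad = set(seq) - VALID_BASES
            if bad:
                raise VariantError(
                    f"contig {name!r} contains non-DNA characters: {sorted(bad)}"
                )
            clean[canonical_chrom(name)] = seq
        self.contigs = clean

    @classmethod
    def from_fasta(cls, path: str) -> "ReferenceSequence":
        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.contigs.items()}

    def _contig(self, chrom: str) -> str:
        key = canonical_chrom(chrom)
        if key not in self.contigs:
            raise VariantError(f"unknown contig {chrom!r}")
        return key

    def base(self, chrom: str, pos: int) -> str:
        return self.slice(chrom, pos, pos)

    def slice(self, chrom: str, start: int, end: int) -> str:
        """Bases [start, end], 1-based inclusive."""
        key = self._contig(chrom)
        n = len(self.contigs[key])
        if not (1 <= start <= end <= n):
            raise VariantError(
                f"positions {start}-{end} outside [1, {n}] on {key}"
            )
        return self.contigs[key][start - 1 : end]

    def to_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.contigs, key=contig_sort_key):
                fh.write(f">{name}\n")
                seq = self.contigs[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# variant
# ---------------------------------------------------------------------------

_ALLELE_RE = re.compile(r"^[ACGTN]+$")


def variant_type(ref: str, alt: str) -> str:
    """Type is a pure function of allele lengths."""
    if len(ref) == len(alt):
        return SNV if len(ref) == 1 else MNV
    return INS if len(alt) > len(ref) else DEL


@dataclass(frozen=True, order=True)
class Variant:
    """One allele change: contig, 1-based leftmost position, REF, ALT."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", canonical_chrom(self.chrom))
        for label, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not _ALLELE_RE.match(allele.upper()):
                raise VariantError(f"invalid {label} allele {allele!r}")
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())
        if self.ref == self.alt:
            raise VariantError(f"ref equals alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise VariantError(f"position must be >= 1, got {self.pos}")

    @property
    def vtype(self) -> str:
        return variant_type(self.ref, self.alt)

    @property
    def end(self) -> int:
        """Last reference base covered by REF (1-based inclusive)."""
        return self.pos + len(self.ref) - 1

    def sort_key(self) -> tuple:
        return (*contig_sort_key(self.chrom), self.pos, self.ref, self.alt)


def check_reference(v: Variant, ref: ReferenceSequence) -> None:
    observed = ref.slice(v.chrom, v.pos, v.end)
    if observed != v.ref:
        raise VariantError(
            f"reference mismatch at {v.chrom}:{v.pos}: variant says {v.ref!r}, "
            f"reference has {observed!r}"
        )


def trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Reference-free parsimony: strip shared suffix, then shared prefix.

    An indel keeps one shared anchor base on the left; a same-length change
    is trimmed down to the minimal differing block.
    """
    # shared suffix
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # shared prefix; keep the final shared base as the indel anchor
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def normalize_variant(v: Variant, ref: ReferenceSequence) -> Variant:
    """Unique parsimonious, maximally left-aligned representation.

    Applying input and output to the reference yields the same alternate
    haplotype, and the result is a fixed point of this function.
    """
    check_reference(v, ref)
    pos, r, a = v.pos, v.ref, v.alt

    # iterative left-alignment: truncate equal last bases; when an allele
    # empties, pull in the preceding reference base on the left
    while True:
        if r and a and r[-1] == a[-1] and (len(r) > 1 or len(a) > 1):
            r, a = r[:-1], a[:-1]
            if r and a:
                continue
        if not r or not a:
            if pos > 1:
                prev = ref.base(v.chrom, pos - 1)
                r, a = prev + r, prev + a
                pos -= 1
                continue
            # indel shifted against the contig start: anchor on the right
            nxt = ref.base(v.chrom, pos + len(r))
            r, a = r + nxt, a + nxt
            break
        break
    # strip shared leading bases (keep anchor for indels)
    while len(r) > 1 and len(a) > 1 and r[0] == a[0]:
        r, a = r[1:], a[1:]
        pos += 1
    out = Variant(v.chrom, pos, r, a)
    check_reference(out, ref)
    return out


def split_multiallelic(chrom: str, pos: int, ref: str, alts: Sequence[str]) -> list[Variant]:
    """One variant per ALT allele with reference-free per-allele trimming.

    Results still require :func:`normalize_variant` for left-alignment; order
    of the input ALTs is preserved.
    """
    if not alts:
        raise VariantError("multiallelic record with no alt alleles")
    out = []
    for alt in alts:
        if alt.upper() == ref.upper():
            raise VariantError(f"alt equals ref ({ref!r}) at {chrom}:{pos}")
        p, r, a = trim_alleles(pos, ref.upper(), alt.upper())
        out.append(Variant(chrom, p, r, a))
    return out


def decompose_mnv(v: Variant) -> list[Variant]:
    """Split a multi-nucleotide substitution into its component SNVs.

    By default MNVs are kept whole to preserve caller intent; this opt-in
    decomposition is for joining against SNV-keyed databases.  Non-MNV
    input is returned unchanged (as a single-element list).
    """
    if v.vtype != MNV:
        return [v]
    return [
        Variant(v.chrom, v.pos + i, r, a)
        for i, (r, a) in enumerate(zip(v.ref, v.alt))
        if r != a
    ]


def variant_key(v: Variant, ref: ReferenceSequence | None = None) -> str:
    """Canonical join key ``chrom:pos:ref>alt`` for a normalized variant.

    When a reference is supplied, non-normalized input is refused (checked
    by re-normalizing).
    """
    if ref is not None and normalize_variant(v, ref) != v:
        raise VariantError(f"variant {v} is not normalized; refuse to build key")
    return f"{v.chrom}:{v.pos}:{v.ref}>{v.alt}"


def apply_to_window(v: Variant, window_seq: str, window_start: int) -> str:
    """Apply a variant to a reference window; returns the edited string.

    ``window_seq`` covers 1-based positions ``window_start ..
    window_start+len-1`` and must contain the whole REF allele.  Used to
    assert haplotype equivalence between variant representations.
    """
    off = v.pos - window_start
    if off < 0 or off + len(v.ref) > len(window_seq):
        raise VariantError("variant does not fit in window")
    if window_seq[off : off + len(v.ref)] != v.ref:
        raise VariantError("reference mismatch inside window")
    return window_seq[:off] + v.alt + window_seq[off + len(v.ref) :]


# ---------------------------------------------------------------------------
# variant table
# ---------------------------------------------------------------------------


@dataclass
class VariantRow:
    """A normalized variant plus per-caller flags, quality and annotations."""

    variant: Variant
    caller_flags: dict[str, bool] = field(default_factory=dict)
    vaf: float = 0.0
    depth: int = 0
    mean_base_quality: float = 0.0
    region_type: str = "other"
    gene: str = ""
    effect: str = ""
    annotations: dict[str, str] = field(default_factory=dict)
    a_score: float = 0.0
    p_score: float = 0.0
    classification: str = UNSCORED

    @property
    def caller_count(self) -> int:
        return sum(1 for v in self.caller_flags.values() if v)

    @property
    def key(self) -> str:
        return variant_key(self.variant)

    def copy(self) -> "VariantRow":
        return replace(
            self,
            caller_flags=dict(self.caller_flags),
            annotations=dict(self.annotations),
        )


#: columns every row exposes to expression evaluation regardless of the
#: annotation registry
BUILTIN_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "type",
    "VAF",
    "DP",
    "MBQ",
    "caller_count",
    "region_type",
    "gene",
    "effect",
    "classification",
)


def row_field(row: VariantRow, name: str) -> str:
    """Unified string accessor used by scoring expressions and TSV export.

    Missing values are the empty string — the single missingness convention
    shared with the annotation store and the scoring engine.
    """
    v = row.variant
    builtin = {
        "chrom": v.chrom,
        "pos": str(v.pos),
        "ref": v.ref,
        "alt": v.alt,
        "type": v.vtype,
        "VAF": repr(row.vaf),
        "DP": str(row.depth),
        "MBQ": repr(row.mean_base_quality),
        "caller_count": str(row.caller_count),
        "region_type": row.region_type,
        "gene": row.gene,
        "effect": row.effect,
        "classification": row.classification,
    }
    if name in builtin:
        return builtin[name]
    return row.annotations.get(name, "")


@dataclass
class VariantTable:
    """One row per unique normalized variant, sorted by genome position."""

    sample_id: str
    rows: list[VariantRow] = field(default_factory=list)
    column_registry: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sort()
        keys = [r.key for r in self.rows]
        dupes = {k for k in keys if keys.count(k) > 1}
        if dupes:
            raise VariantError(f"duplicate normalized keys in table: {sorted(dupes)}")

    def sort(self) -> None:
        self.rows.sort(key=lambda r: r.variant.sort_key())

    @property
    def keys(self) -> list[str]:
        return [r.key for r in self.rows]

    def __len__(self) -> int:
        return len(self.rows)

    def copy(self) -> "VariantTable":
        return VariantTable(
            self.sample_id,
            [r.copy() for r in self.rows],
            list(self.column_registry),
        )

    def register_columns(self, names: Iterable[str]) -> None:
        for n in names:
            if n not in self.column_registry:
                self.column_registry.append(n)

    def to_dataframe(self) -> pd.DataFrame:
        cols = list(BUILTIN_COLUMNS) + ["a_score", "p_score"] + [
            c for c in self.column_registry if c not in BUILTIN_COLUMNS
        ]
        callers = sorted({c for r in self.rows for c in r.caller_flags})
        data = []
        for r in self.rows:
            rec = {c: row_field(r, c) for c in cols}
            rec["a_score"] = r.a_score
            rec["p_score"] = r.p_score
            rec["key"] = r.key
            for c in callers:
                rec[f"called_by.{c}"] = int(bool(r.caller_flags.get(c)))
            data.append(rec)
        frame_cols = ["key"] + cols + [f"called_by.{c}" for c in callers]
        return pd.DataFrame(data, columns=frame_cols)

    def to_tsv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# table filtering (the interactive-explorer semantics)
# ---------------------------------------------------------------------------


@dataclass
class FilterCriteria:
    """Conjunctive row filter: gene/region membership, quality minima,
    optional exclusion of artifact/polymorphism classifications, and extra
    per-column numeric minima."""

    genes: set[str] | None = None
    region_types: set[str] | None = None
    min_depth: int = 0
    min_vaf: float = 0.0
    min_base_quality: float = 0.0
    exclude_artifacts: bool = False
    exclude_polymorphisms: bool = False
    column_minima: dict[str, float] = field(default_factory=dict)


def filter_table(table: VariantTable, criteria: FilterCriteria) -> VariantTable:
    """Rows satisfying the conjunction of all criteria; input unmodified."""
    known = set(BUILTIN_COLUMNS) | set(table.column_registry)
    unknown = set(criteria.column_minima) - known
    if unknown:
        raise VariantError(
            f"unknown filter column(s) {sorted(unknown)}; valid columns: {sorted(known)}"
        )

    def keep(r: VariantRow) -> bool:
        if criteria.genes is not None and r.gene not in criteria.genes:
            return False
        if criteria.region_types is not None and r.region_type not in criteria.region_types:
            return False
        if r.depth < criteria.min_depth or r.vaf < criteria.min_vaf:
            return False
        if r.mean_base_quality < criteria.min_base_quality:
            return False
        if criteria.exclude_artifacts and r.classification in (
            ARTIFACT,
            ARTIFACT_AND_POLYMORPHISM,
        ):
            return False
        if criteria.exclude_polymorphisms and r.classification in (
            POLYMORPHISM,
            ARTIFACT_AND_POLYMORPHISM,
        ):
            return False
        for col, minimum in criteria.column_minima.items():
            raw = row_field(r, col)
            try:
                val = float(raw)
            except ValueError:
                return False
            if val < minimum:
                return False
        return True

    return VariantTable(
        table.sample_id,
        [r.copy() for r in table.rows if keep(r)],
        list(table.column_registry),
    )
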