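"""Truth-set comparison: confusion counts, sensitivity and PPV.

Calls are matched against a validated truth set by exact equality of
normalized variant keys — normalization, not fuzzy windowing, is what
reconciles representation differences.  An optional region restriction
(e.g. "hotspot regions only") is applied to both sides before counting.

Sensitivity = TP / (TP + FN); PPV = TP / (TP + FP); both rounded half-up
to four decimals.  A zero denominator yields not-available (None), never 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

from .variants import (
    ReferenceSequence,
    Variant,
    VariantError,
    VariantTable,
    canonical_chrom,
    normalize_variant,
    variant_key,
)


@dataclass
class ConfusionCounts:
    """TP/FP/FN for one call set against one truth set."""

    tp: int
    fp: int
    fn: int
    n_samples: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise VariantError("confusion counts must be non-negative")

    @property
    def n_true(self) -> int:
        return self.tp + self.fn

    @property
    def n_called(self) -> int:
        return self.tp + self.fp

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.n_samples + other.n_samples,
        )


@dataclass
class MetricsResult:
    sensitivity: float | None
    ppv: float | None


def _round4(numerator: int, denominator: int) -> float | None:
    if denominator == 0:
        return None
    q = Decimal(numerator) / Decimal(denominator)
    return float(q.quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP))


def compute_metrics(c: ConfusionCounts) -> MetricsResult:
    """Sensitivity and PPV, rounded half-up to 4 decimal places."""
    return MetricsResult(
        sensitivity=_round4(c.tp, c.tp + c.fn),
        ppv=_round4(c.tp, c.tp + c.fp),
    )


def _in_region(v: Variant, region: Sequence[tuple[str, int, int]]) -> bool:
    chrom = canonical_chrom(v.chrom)
    for rchrom, start, end in region:
        if chrom == canonical_chrom(rchrom) and v.pos <= end and v.end >= start:
            return True
    return False


def match_calls(
    called: VariantTable,
    truth: Sequence[Variant],
    region: Sequence[tuple[str, int, int]] | None = None,
    ref: ReferenceSequence | None = None,
) -> ConfusionCounts:
    """Confusion counts by exact normalized-key matching.

    ``region`` is a list of 1-based inclusive intervals applied to both
    sides before counting.  A truth set with duplicate normalized keys is
    ill-formed and rejected.  When a reference is given, truth variants are
    normalized first; otherwise they must already be canonical.
    """
    truth_norm = [normalize_variant(t, ref) if ref else t for t in truth]
    truth_keys = [variant_key(t) for t in truth_norm]
    dupes = {k for k in truth_keys if truth_keys.count(k) > 1}
    if dupes:
        raise VariantError(f"truth set contains duplicate keys: {sorted(dupes)}")

    if region is not None:
        truth_set = {
            k for k, t in zip(truth_keys, truth_norm) if _in_region(t, region)
        }
        called_keys = {
            r.key for r in called.rows if _in_region(r.variant, region)
        }
    else:
        truth_set = set(truth_keys)
        called_keys = set(called.keys)

    tp = len(called_keys & truth_set)
    return ConfusionCounts(
        tp=tp,
        fp=len(called_keys - truth_set),
        fn=len(truth_set - called_keys),
        n_samples=1,
    )


def summarize(datasets: Sequence[tuple[str, ConfusionCounts]]) -> pd.DataFrame:
    """One row per dataset (label, counts, metrics); TSV-exportable.

    The same shape serves per-gene grouping: pass one entry per gene and
    the columns read n, detected (TP), missed (FN), sensitivity and PPV.
    """
    if not datasets:
        raise VariantError("summarize needs at least one dataset")
    rows = []
    for label, c in datasets:
        m = compute_metrics(c)
        rows.append(
            {
                "label": label,
                "n_samples": c.n_samples,
                "n_true": c.n_true,
                "n_called": c.n_called,
                "tp": c.tp,
                "fp": c.fp,
                "fn": c.fn,
                "sensitivity": m.sensitivity,
                "ppv": m.ppv,
            }
        )
    return pd.DataFrame(rows)


def read_truth_set(path: str, ref: ReferenceSequence) -> list[Variant]:
    """Truth set from a VCF or a 4-column TSV (chrom, pos, ref, alt)."""
    p = str(path)
    variants: list[Variant] = []
    if p.endswith((".vcf", ".vcf.gz")):
        import pysam

        with pysam.VariantFile(p) as vcf:
            for rec in vcf:
                for alt in rec.alts or ():
                    variants.append(
                        normalize_variant(Variant(rec.chrom, rec.pos, rec.ref, alt), ref)
                    )
        return variants
    with open(p) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            chrom, pos, r, a = line.split("\t")[:4]
            variants.append(normalize_variant(Variant(chrom, int(pos), r, a), ref))
    return variants
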