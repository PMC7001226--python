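"""Versioned annotation sources joined onto the variant table at read time.

Variant lists and annotation tables live apart and are merged only when a
table is retrieved, so a database update never requires re-processing
samples: swap the snapshot, re-join, and the scoring scheme sees the new
columns.  Every snapshot carries a content fingerprint (a digest of its
source name/version pairs) that goes into report provenance, making any
past report's annotation state reconstructable.

Missing values are the empty string everywhere — the same convention the
scoring engine's ``isEmpty()`` tests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import pysam

from .variants import (
    ReferenceSequence,
    Variant,
    VariantError,
    VariantTable,
    normalize_variant,
    variant_key,
)

logger = logging.getLogger("varan")


@dataclass
class AnnotationSource:
    """One annotation database: normalized variant key -> column -> value."""

    source_name: str
    version_label: str
    records: dict[str, dict[str, str]] = field(default_factory=dict)
    columns: list[str] = field(default_factory=list)

    def prefixed_columns(self) -> list[str]:
        return [f"{self.source_name}.{c}" for c in self.columns]


@dataclass
class AnnotationSnapshot:
    """A fixed set of annotation sources at fixed versions."""

    sources: list[AnnotationSource] = field(default_factory=list)

    @property
    def snapshot_id(self) -> str:
        return snapshot_fingerprint(self)


def snapshot_fingerprint(snap: AnnotationSnapshot) -> str:
    """Order-invariant hex digest over (source_name, version_label) pairs.

    The empty snapshot digests the empty string:
    e3b0c44298fc1c149afbf4c8996fb92427ae41e4649b934ca495991b7852b855.
    """
    payload = "\n".join(
        sorted(f"{s.source_name}:{s.version_label}" for s in snap.sources)
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def _ingest(
    source: AnnotationSource,
    variant: Variant,
    values: Mapping[str, str],
    ref: ReferenceSequence,
    context: str,
) -> None:
    try:
        key = variant_key(normalize_variant(variant, ref))
    except VariantError as exc:
        logger.warning("%s: skipping unnormalizable record: %s", context, exc)
        return
    if key in source.records:
        logger.warning(
            "%s: duplicate key %s after normalization; keeping first record",
            context,
            key,
        )
        return
    source.records[key] = {k: str(v) for k, v in values.items()}


def load_annotation_table(
    path: str, source_name: str, version_label: str, ref: ReferenceSequence
) -> AnnotationSource:
    """Load a TSV (chrom, pos, ref, alt, value columns) or VCF source.

    Every record's variant is normalized against the reference; records that
    collapse onto an existing key are dropped with a warning (first wins).
    For VCF input the INFO keys become the value columns; flags become "1".
    """
    source = AnnotationSource(source_name, version_label)
    p = str(path)
    if p.endswith((".vcf", ".vcf.gz")):
        with pysam.VariantFile(p) as vcf:
            info_keys = list(vcf.header.info)
            source.columns = info_keys
            for rec in vcf:
                for alt in rec.alts or ():
                    if set(alt.upper()) - set("ACGT"):
                        continue
                    values = {}
                    for k in info_keys:
                        if k in rec.info:
                            raw = rec.info[k]
                            if raw is True:
                                values[k] = "1"
                            elif isinstance(raw, tuple):
                                values[k] = ",".join(str(x) for x in raw)
                            else:
                                values[k] = str(raw)
                        else:
                            values[k] = ""
                    _ingest(
                        source,
                        Variant(rec.chrom, rec.pos, rec.ref, alt),
                        values,
                        ref,
                        f"{path}:{rec.chrom}:{rec.pos}",
                    )
        return source

    frame = pd.read_csv(p, sep="\t", dtype=str).fillna("")
    mandatory = ["chrom", "pos", "ref", "alt"]
    missing = [c for c in mandatory if c not in frame.columns]
    if missing:
        raise VariantError(f"{path}: missing mandatory column(s) {missing}")
    source.columns = [c for c in frame.columns if c not in mandatory]
    for idx, rec in frame.iterrows():
        try:
            variant = Variant(rec["chrom"], int(rec["pos"]), rec["ref"], rec["alt"])
        except (VariantError, ValueError) as exc:
            logger.warning("%s: row %s skipped: %s", path, idx, exc)
            continue
        _ingest(
            source,
            variant,
            {c: rec[c] for c in source.columns},
            ref,
            f"{path}: row {idx}",
        )
    return source


def load_snapshot(manifest_path: str, ref: ReferenceSequence) -> AnnotationSnapshot:
    """Load a snapshot manifest: JSON list of
    ``{"source_name", "version_label", "path"}`` (paths relative to the
    manifest's directory)."""
    manifest_path = Path(manifest_path)
    entries = json.loads(manifest_path.read_text())
    if isinstance(entries, dict):
        entries = entries["sources"]
    sources = []
    for e in entries:
        path = Path(e["path"])
        if not path.is_absolute():
            path = manifest_path.parent / path
        sources.append(
            load_annotation_table(str(path), e["source_name"], e["version_label"], ref)
        )
    return AnnotationSnapshot(sources)


def annotate(table: VariantTable, snap: AnnotationSnapshot) -> VariantTable:
    """Left-join all snapshot sources onto the table by variant key.

    Unmatched rows receive empty strings in every annotation column.
    Columns are prefixed ``source_name.`` so sources cannot collide.
    Re-annotating with the same snapshot is a no-op; re-annotating with a
    newer version of one source changes only that source's columns.
    The input table is unmodified.
    """
    out = table.copy()
    for source in snap.sources:
        prefix = f"{source.source_name}."
        # drop any stale columns from a previous version of this source
        for row in out.rows:
            for col in [c for c in row.annotations if c.startswith(prefix)]:
                del row.annotations[col]
        out.column_registry = [
            c for c in out.column_registry if not c.startswith(prefix)
        ]
        out.register_columns(source.prefixed_columns())
        for row in out.rows:
            values = source.records.get(row.key, {})
            for col in source.columns:
                row.annotations[prefix + col] = values.get(col, "")
    return out
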