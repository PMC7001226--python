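"""Synthetic targeted-panel data: every input the pipeline consumes.

The generator emulates a deep targeted amplicon panel of the kind used in
myeloid-malignancy diagnostics: a ~42 kbp target with repeat tracts,
hundreds of validated somatic variants at VAFs down to a few percent,
~1450x mean coverage with localized dips, eight variant callers with
individual sensitivities and false-positive rates that sometimes emit
non-normalized representations, per-base readcounts, annotation tables
(dbSNP-like membership with a PM flag, population allele frequencies,
COSMIC-like occurrence counts, clinical significance), a hotspot site
registry and a diagnostic rulebook.

Everything is a pure function of the configuration and the seed; each
output file draws from its own random stream keyed by (seed, file role),
so adding a caller never perturbs any other file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .variants import (
    ReferenceSequence,
    Variant,
    VariantError,
    normalize_variant,
    variant_key,
)

BASES = np.array(list("ACGT"))


def rng_for(seed: int, role: str) -> np.random.Generator:
    """One independent, reproducible stream per (seed, output role)."""
    role_int = int.from_bytes(hashlib.sha256(role.encode()).digest()[:4], "big")
    return np.random.default_rng([int(seed) % (2**31), role_int])


@dataclass(frozen=True)
class CallerProfile:
    """Error model of one simulated variant caller."""

    caller_id: str
    sensitivity: float = 0.9  # per-variant detection probability
    fp_rate: float = 0.5  # expected false calls per kbp of target
    denormalize_prob: float = 0.0  # chance of a shifted/padded emission

    def __post_init__(self) -> None:
        if not (0 <= self.sensitivity <= 1 and 0 <= self.denormalize_prob <= 1):
            raise VariantError("probabilities must lie in [0, 1]")
        if self.fp_rate < 0:
            raise VariantError("fp_rate must be >= 0")


def default_profiles() -> tuple[CallerProfile, ...]:
    """Eight callers with spread sensitivities, echoing how real ensembles
    of calling tools produce highly differing result lists."""
    spec = [
        ("gatk", 0.95, 0.5, 0.3),
        ("freebayes", 0.92, 0.5, 0.3),
        ("samtools", 0.90, 0.5, 0.2),
        ("lofreq", 0.88, 0.4, 0.0),
        ("platypus", 0.85, 0.5, 0.4),
        ("snver", 0.80, 0.6, 0.0),
        ("varscan", 0.75, 0.5, 0.2),
        ("vardict", 0.70, 0.6, 0.4),
    ]
    return tuple(CallerProfile(n, s, f, d) for n, s, f, d in spec)


@dataclass
class SimulationConfig:
    """Fully determines every generated file given the seed."""

    seed: int = 0
    contig: str = "chr1"
    reference_length: int = 42_000
    n_truth_variants: int = 500
    vaf_min: float = 0.05
    vaf_max: float = 0.60
    coverage_mean: float = 1450.0
    coverage_floor: int = 300
    #: (start 1-based, length, depth) windows forced below wild-type depth
    dips: tuple[tuple[int, int, int], ...] = ((8_000, 10, 30), (30_000, 25, 40))
    profiles: tuple[CallerProfile, ...] = field(default_factory=default_profiles)
    fp_noise_vaf: float = 0.03
    snv_fraction: float = 0.70
    ins_fraction: float = 0.15
    synonymous_fraction: float = 0.10
    n_repeat_tracts: int = 8
    repeat_tract_length: int = 12
    fraction_dbsnp: float = 0.25
    fraction_pm: float = 0.50  # of dbSNP members
    fraction_cosmic: float = 0.30
    fraction_benign: float = 0.04
    n_genes: int = 14

    def __post_init__(self) -> None:
        if self.reference_length < 1000:
            raise VariantError("reference length must be >= 1 kbp")
        if not (0 < self.vaf_min <= self.vaf_max <= 1):
            raise VariantError("need 0 < vaf_min <= vaf_max <= 1")
        # drop dip windows that do not fit the target (the defaults are
        # sized for the default reference length)
        fitting = tuple(
            (s, l, d) for s, l, d in self.dips
            if s >= 1 and s + l - 1 <= self.reference_length
        )
        if fitting != tuple(self.dips):
            import logging

            logging.getLogger("varan").warning(
                "dropping %d dip window(s) outside the %d bp target",
                len(self.dips) - len(fitting), self.reference_length,
            )
            self.dips = fitting


@dataclass
class TruthVariant:
    """A planted variant plus the hidden state the pipeline must recover."""

    variant: Variant
    vaf: float
    gene: str
    effect: str
    in_dbsnp: bool = False
    pm_flag: bool = False
    popfreq_af: float = 0.0
    cosmic_occurrence: int = 0
    clinsig: str = ""

    @property
    def key(self) -> str:
        return variant_key(self.variant)


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------


def generate_reference(
    cfg: SimulationConfig,
) -> tuple[ReferenceSequence, list[tuple[str, int, int]], list[tuple[int, int]]]:
    """Seeded random reference with planted repeat tracts.

    Returns the sequence, the target BED (0-based half-open triples) and
    the list of repeat-tract intervals (1-based inclusive) for downstream
    placement of normalization-stressing indels.
    """
    rng = rng_for(cfg.seed, "reference")
    seq = rng.choice(BASES, size=cfg.reference_length)
    tracts: list[tuple[int, int]] = []
    n_each = max(1, cfg.n_repeat_tracts // 2)
    slots = rng.choice(
        np.arange(200, cfg.reference_length - 200, 400),
        size=min(cfg.n_repeat_tracts, (cfg.reference_length - 400) // 400),
        replace=False,
    )
    for i, start0 in enumerate(sorted(int(s) for s in slots)):
        L = cfg.repeat_tract_length
        if i < n_each:  # dinucleotide tract, e.g. CACACA...
            unit = "".join(rng.choice(BASES, size=2))
            while unit[0] == unit[1]:
                unit = "".join(rng.choice(BASES, size=2))
            tract = (unit * L)[:L]
        else:  # homopolymer
            tract = str(rng.choice(BASES)) * L
        seq[start0 : start0 + L] = list(tract)
        tracts.append((start0 + 1, start0 + L))
    ref = ReferenceSequence({cfg.contig: "".join(seq)})
    bed = [(cfg.contig, 0, cfg.reference_length)]
    return ref, bed, tracts


# ---------------------------------------------------------------------------
# truth variants
# ---------------------------------------------------------------------------


def _gene_of(pos: int, cfg: SimulationConfig) -> str:
    block = cfg.reference_length // cfg.n_genes + 1
    return f"GENE{pos // block + 1:02d}"


def plant_truth_variants(
    ref: ReferenceSequence,
    cfg: SimulationConfig,
    tracts: Sequence[tuple[int, int]] = (),
) -> list[TruthVariant]:
    """Plant SNVs and small indels at unique normalized keys.

    At least one indel lands inside a repeat tract (when tracts exist), so
    the caller-dialect machinery has something to denormalize.  Anchor
    positions keep >= 15 bp spacing; variants therefore never interact.
    """
    rng = rng_for(cfg.seed, "truth")
    contig = cfg.contig
    n = cfg.n_truth_variants
    if n == 0:
        return []
    grid = np.arange(20, cfg.reference_length - 20, 15)
    # keep planted variants clear of repeat tracts (except the forced ones)
    # and of coverage-dip windows: a validated truth variant on a dead
    # amplicon would confound the coverage analysis
    mask = np.zeros(len(grid), dtype=bool)
    for start, end in tracts:
        mask |= (grid >= start - 18) & (grid <= end + 3)
    for start, dip_len, _depth in cfg.dips:
        mask |= (grid >= start - 8) & (grid <= start + dip_len + 3)
    free = grid[~mask]
    if n > len(free):
        raise VariantError(f"cannot place {n} variants on this target")
    positions = sorted(int(p) for p in rng.choice(free, size=n, replace=False))

    out: list[TruthVariant] = []
    seen: set[str] = set()
    kinds = rng.random(n)
    vafs = rng.uniform(cfg.vaf_min, cfg.vaf_max, size=n)
    syn = rng.random(n) < cfg.synonymous_fraction

    def make(pos: int, kind: float) -> tuple[Variant, str]:
        anchor = ref.base(contig, pos)
        if kind < cfg.snv_fraction:  # SNV
            alt = str(rng.choice([b for b in "ACGT" if b != anchor]))
            return Variant(contig, pos, anchor, alt), "snv"
        if kind < cfg.snv_fraction + cfg.ins_fraction:  # insertion
            ins = "".join(rng.choice(BASES, size=int(rng.integers(1, 5))))
            return Variant(contig, pos, anchor, anchor + ins), "ins"
        length = int(rng.integers(1, 5))
        deleted = ref.slice(contig, pos, pos + length)
        return Variant(contig, pos, deleted, deleted[0]), "del"

    for i, (pos, kind) in enumerate(zip(positions, kinds)):
        v, shape = make(pos, kind)
        v = normalize_variant(v, ref)
        if variant_key(v) in seen:
            continue
        seen.add(variant_key(v))
        if shape == "snv":
            effect = "synonymous" if syn[i] else "nonsynonymous"
        else:
            indel_len = abs(len(v.ref) - len(v.alt))
            effect = "frameshift" if indel_len % 3 else "inframe_indel"
        out.append(
            TruthVariant(v, float(vafs[i]), _gene_of(pos, cfg), effect)
        )

    # force >= 1 indel inside a repeat tract
    if tracts:
        start, end = tracts[0]
        pos = start + 1
        anchor = ref.base(contig, pos)
        unit = ref.slice(contig, pos + 1, pos + 2)
        v = normalize_variant(
            Variant(contig, pos, anchor + unit, anchor), ref
        )
        if variant_key(v) not in seen:
            seen.add(variant_key(v))
            out.append(
                TruthVariant(
                    v,
                    float(rng.uniform(cfg.vaf_min, cfg.vaf_max)),
                    _gene_of(pos, cfg),
                    "frameshift",
                )
            )

    _assign_annotation_state(out, cfg)
    out.sort(key=lambda t: t.variant.sort_key())
    return out


def _assign_annotation_state(truth: list[TruthVariant], cfg: SimulationConfig) -> None:
    """Draw the hidden database memberships each truth variant will show."""
    rng = rng_for(cfg.seed, "annotation-state")
    for t in truth:
        if rng.random() < cfg.fraction_dbsnp:
            t.in_dbsnp = True
            t.pm_flag = bool(rng.random() < cfg.fraction_pm)
            t.popfreq_af = float(rng.uniform(0.0005, 0.05))
        if rng.random() < cfg.fraction_cosmic:
            t.cosmic_occurrence = int(rng.integers(1, 60))
        if rng.random() < cfg.fraction_benign:
            t.clinsig = str(rng.choice(["benign", "likely_benign"]))
        elif t.cosmic_occurrence > 0 and rng.random() < 0.5:
            t.clinsig = "pathogenic"


# ---------------------------------------------------------------------------
# caller outputs
# ---------------------------------------------------------------------------


def _right_shift(v: Variant, ref: ReferenceSequence, steps: int) -> Variant:
    """Shift an indel right by up to ``steps`` haplotype-preserving moves
    (mirror of left-alignment); returns an equivalent representation."""
    pos, r, a = v.pos, v.ref, v.alt
    length = len(ref.contigs[v.chrom])
    for _ in range(steps):
        if r and a and r[0] == a[0] and (len(r) > 1 or len(a) > 1):
            r, a, pos = r[1:], a[1:], pos + 1
            if r and a:
                continue
        if not r or not a:
            nxt_pos = pos + len(r)
            if nxt_pos > length:
                break
            nxt = ref.base(v.chrom, nxt_pos)
            r, a = r + nxt, a + nxt
            continue
        break
    if not r or not a:  # re-anchor on the left
        prev = ref.base(v.chrom, pos - 1)
        r, a, pos = prev + r, prev + a, pos - 1
    return Variant(v.chrom, pos, r, a)


def denormalized_representation(
    v: Variant, ref: ReferenceSequence, rng: np.random.Generator
) -> Variant:
    """An equivalent but non-canonical emission: right-shifted within its
    repeat context and/or padded with flanking reference bases."""
    out = v
    if v.vtype in ("INS", "DEL") and rng.random() < 0.7:
        out = _right_shift(out, ref, int(rng.integers(1, 9)))
    # pad with flanking reference bases (untrimmed representation)
    pad_left = int(rng.integers(0, 3))
    pad_right = int(rng.integers(0, 3))
    pos, r, a = out.pos, out.ref, out.alt
    length = len(ref.contigs[v.chrom])
    for _ in range(pad_left):
        if pos <= 1:
            break
        prev = ref.base(v.chrom, pos - 1)
        pos, r, a = pos - 1, prev + r, prev + a
    for _ in range(pad_right):
        nxt_pos = pos + len(r)
        if nxt_pos > length:
            break
        nxt = ref.base(v.chrom, nxt_pos)
        r, a = r + nxt, a + nxt
    if r == a:  # degenerate (cannot happen for real variants); keep original
        return v
    return Variant(v.chrom, pos, r, a)


def _write_vcf(path: Path, ref: ReferenceSequence, rows: list[tuple]) -> None:
    lines = ["##fileformat=VCFv4.2"]
    for contig, seq in ref.contigs.items():
        lines.append(f"##contig=<ID={contig},length={len(seq)}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for chrom, pos, r, a, qual in sorted(rows, key=lambda x: (x[0], x[1], x[2], x[3])):
        q = f"{qual:.1f}" if qual is not None else "."
        lines.append(f"{chrom}\t{pos}\t.\t{r}\t{a}\t{q}\tPASS\t.")
    path.write_text("\n".join(lines) + "\n")


def simulate_caller_outputs(
    truth: Sequence[TruthVariant],
    profiles: Sequence[CallerProfile],
    ref: ReferenceSequence,
    cfg: SimulationConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write one VCF 4.2 per caller.

    Each truth variant is detected independently with the caller's
    sensitivity; false-positive SNVs are placed uniformly over the target
    (never on a truth variant's neighborhood, so false calls and true calls
    stay analytically separable); with ``denormalize_prob`` an equivalent
    non-canonical representation is written instead of the canonical one.
    """
    if not profiles:
        raise VariantError("need at least one caller profile")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    length = cfg.reference_length
    blocked = np.zeros(length + 2, dtype=bool)
    for t in truth:
        lo = max(1, t.variant.pos - 8)
        hi = min(length, t.variant.end + 8)
        blocked[lo : hi + 1] = True
    allowed = np.array(
        [p for p in range(10, length - 10) if not blocked[p]], dtype=int
    )

    paths: dict[str, Path] = {}
    for prof in profiles:
        rng = rng_for(cfg.seed, f"caller:{prof.caller_id}")
        rows = []
        for t in truth:
            if rng.random() >= prof.sensitivity:
                continue
            v = t.variant
            if rng.random() < prof.denormalize_prob:
                v = denormalized_representation(v, ref, rng)
            rows.append((v.chrom, v.pos, v.ref, v.alt, float(rng.uniform(30, 90))))
        n_fp = int(rng.poisson(prof.fp_rate * length / 1000.0))
        n_fp = min(n_fp, len(allowed))
        for p in rng.choice(allowed, size=n_fp, replace=False):
            pos = int(p)
            anchor = ref.base(cfg.contig, pos)
            alt = str(rng.choice([b for b in "ACGT" if b != anchor]))
            rows.append((cfg.contig, pos, anchor, alt, float(rng.uniform(10, 40))))
        path = out_dir / f"{prof.caller_id}.vcf"
        _write_vcf(path, ref, rows)
        paths[prof.caller_id] = path
    return paths


def expected_fp_keys(
    paths: dict[str, Path], truth: Sequence[TruthVariant], ref: ReferenceSequence
) -> set[str]:
    """Normalized keys emitted by any caller that are not truth keys."""
    from .callers import read_caller_vcf

    truth_keys = {t.key for t in truth}
    fp: set[str] = set()
    for caller_id, path in paths.items():
        out = read_caller_vcf(str(path), caller_id, ref)
        fp |= {variant_key(v) for v in out.variants} - truth_keys
    return fp


# ---------------------------------------------------------------------------
# readcounts & coverage
# ---------------------------------------------------------------------------


def simulate_readcounts_and_coverage(
    truth: Sequence[TruthVariant],
    fp_keys: Sequence[str],
    ref: ReferenceSequence,
    cfg: SimulationConfig,
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Write the per-base readcount TSV and a BEDGRAPH coverage track.

    Depth is ``floor + Poisson(mean - floor)`` per base, overridden to the
    configured constant inside dip windows.  Supporting-allele counts at
    truth sites are Binomial(depth, VAF); false-positive sites carry
    low-level noise counts at ``fp_noise_vaf`` so that false calls face the
    scoring scheme rather than dying trivially at the readcount stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = rng_for(cfg.seed, "readcounts")
    length = cfg.reference_length
    depth = cfg.coverage_floor + rng.poisson(
        max(cfg.coverage_mean - cfg.coverage_floor, 0), size=length + 1
    )
    depth[0] = 0
    for start, dip_len, dip_depth in cfg.dips:
        depth[start : start + dip_len] = dip_depth

    from .callers import supporting_allele_key

    def record_line(pos: int, alleles: dict[str, float]) -> str:
        d = int(depth[pos])
        anchor = ref.base(cfg.contig, pos)
        counts: dict[str, int] = {}
        quals: dict[str, float] = {}
        remaining = d
        for allele, vaf in alleles.items():
            c = int(rng.binomial(d, vaf)) if d > 0 else 0
            c = min(c, remaining)
            counts[allele] = c
            quals[allele] = float(np.clip(rng.normal(33, 2), 25, 40))
            remaining -= c
        counts[anchor] = remaining
        quals[anchor] = float(np.clip(rng.normal(34, 1.5), 25, 40))
        triplets = "\t".join(
            f"{al}:{counts[al]}:{quals[al]:.2f}" for al in sorted(counts)
        )
        return f"{cfg.contig}\t{pos}\t{anchor}\t{d}\t{triplets}"

    per_pos: dict[int, dict[str, float]] = {}
    for t in truth:
        allele = supporting_allele_key(t.variant)
        per_pos.setdefault(t.variant.pos, {})[allele] = t.vaf
    for key in fp_keys:
        chrom, pos, change = key.split(":")
        r, a = change.split(">")
        v = Variant(chrom, int(pos), r, a)
        allele = supporting_allele_key(v)
        per_pos.setdefault(v.pos, {}).setdefault(allele, cfg.fp_noise_vaf)

    rc_path = out_dir / "readcounts.tsv"
    with open(rc_path, "w") as fh:
        fh.write("# chrom\tpos\tref\tdepth\tallele:count:mean_bq...\n")
        for pos in sorted(per_pos):
            fh.write(record_line(pos, per_pos[pos]) + "\n")

    cov_path = out_dir / "coverage.bedgraph"
    with open(cov_path, "w") as fh:
        run_start, run_depth = 1, int(depth[1])
        for pos in range(2, length + 1):
            d = int(depth[pos])
            if d != run_depth:
                fh.write(f"{cfg.contig}\t{run_start - 1}\t{pos - 1}\t{run_depth}\n")
                run_start, run_depth = pos, d
        fh.write(f"{cfg.contig}\t{run_start - 1}\t{length}\t{run_depth}\n")
    return rc_path, cov_path


# ---------------------------------------------------------------------------
# annotation tables & snapshots
# ---------------------------------------------------------------------------


def simulate_annotations(
    truth: Sequence[TruthVariant],
    cfg: SimulationConfig,
    out_dir: str | Path,
) -> dict:
    """Write annotation TSVs plus two snapshot manifests.

    The second manifest differs from the first in exactly one dbSNP PM
    flag: the chosen variant is a dbSNP member without PM, with population
    frequency forced above any common-polymorphism threshold and no COSMIC
    record, so flipping PM between snapshot versions flips that variant's
    classification under the shipped default scheme (the database-update
    effect on ratings).  Returns the manifest paths and the flipped key.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = rng_for(cfg.seed, "annotation-files")

    flip_target: TruthVariant | None = None
    for t in truth:
        if t.in_dbsnp and not t.pm_flag:
            flip_target = t
            break
    if flip_target is not None:
        flip_target.popfreq_af = 0.05
        flip_target.cosmic_occurrence = 0
        flip_target.clinsig = ""

    def v_cols(t: TruthVariant) -> str:
        v = t.variant
        return f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}"

    def write_dbsnp(path: Path, pm_flip_key: str | None) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tref\talt\tid\tPM\n")
            for i, t in enumerate(truth):
                if not t.in_dbsnp:
                    continue
                pm = t.pm_flag
                if pm_flip_key is not None and t.key == pm_flip_key:
                    pm = not pm
                fh.write(f"{v_cols(t)}\trs{900000 + i}\t{'1' if pm else ''}\n")

    dbsnp_v1 = out_dir / "dbsnp_v1.tsv"
    dbsnp_v2 = out_dir / "dbsnp_v2.tsv"
    write_dbsnp(dbsnp_v1, None)
    write_dbsnp(dbsnp_v2, flip_target.key if flip_target else None)

    popfreq = out_dir / "popfreq.tsv"
    with open(popfreq, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tAF\n")
        for t in truth:
            if t.in_dbsnp:
                fh.write(f"{v_cols(t)}\t{t.popfreq_af:.6f}\n")

    cosmic = out_dir / "cosmic.tsv"
    with open(cosmic, "w") as fh:
        fh.write("chrom\tpos\tref\talt\toccurrence\n")
        for t in truth:
            if t.cosmic_occurrence > 0:
                fh.write(f"{v_cols(t)}\t{t.cosmic_occurrence}\n")

    clinsig = out_dir / "clinsig.tsv"
    with open(clinsig, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tsignificance\n")
        for t in truth:
            if t.clinsig:
                fh.write(f"{v_cols(t)}\t{t.clinsig}\n")

    effects = out_dir / "effects.tsv"
    with open(effects, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tgene\teffect\tregion_type\n")
        for t in truth:
            fh.write(f"{v_cols(t)}\t{t.gene}\t{t.effect}\texon\n")

    def manifest(path: Path, dbsnp_path: Path, dbsnp_version: str) -> Path:
        doc = [
            {"source_name": "dbsnp", "version_label": dbsnp_version, "path": dbsnp_path.name},
            {"source_name": "popfreq", "version_label": "sim-1", "path": popfreq.name},
            {"source_name": "cosmic", "version_label": "sim-1", "path": cosmic.name},
            {"source_name": "clinsig", "version_label": "sim-1", "path": clinsig.name},
            {"source_name": "effects", "version_label": "sim-1", "path": effects.name},
        ]
        path.write_text(json.dumps(doc, indent=2) + "\n")
        return path

    m1 = manifest(out_dir / "snapshot_v1.json", dbsnp_v1, "sim-150")
    m2 = manifest(out_dir / "snapshot_v2.json", dbsnp_v2, "sim-151")
    return {
        "manifest_v1": m1,
        "manifest_v2": m2,
        "flipped_key": flip_target.key if flip_target else None,
    }


# ---------------------------------------------------------------------------
# site registry & rulebook
# ---------------------------------------------------------------------------


def simulate_sites_and_rules(
    truth: Sequence[TruthVariant],
    cfg: SimulationConfig,
    out_dir: str | Path,
    n_mutated: int = 3,
    n_wildtype: int = 3,
) -> tuple[Path, Path]:
    """Write a hotspot site registry and a diagnostic rulebook.

    Sites are constructed so the three states all occur: ranges over
    planted non-synonymous variants (mutated), over coverage-dip windows
    (insufficiently covered), and over clean well-covered intervals
    (wild type).  Rules exercise both the detection and the safe-exclusion
    direction.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sites = []
    used: list[tuple[int, int]] = []
    def reportable(t: TruthVariant) -> bool:
        # would survive relevance checks and a caller-count/database scheme:
        # non-synonymous, not benign, not a common unflagged database variant
        looks_germline = (
            t.in_dbsnp
            and not t.pm_flag
            and t.popfreq_af >= 0.01
            and t.cosmic_occurrence < 5
        )
        return (
            t.effect != "synonymous"
            and not t.clinsig.endswith("benign")
            and not looks_germline
        )

    eligible = [t for t in truth if reportable(t)]
    for i, t in enumerate(eligible[:n_mutated]):
        start1 = max(1, t.variant.pos - 10)
        end1 = min(cfg.reference_length, t.variant.end + 10)
        used.append((start1, end1))
        sites.append(
            {
                "site_id": f"HS_MUT_{i + 1}",
                "gene": t.gene,
                "label": f"{t.gene} hotspot {i + 1}",
                "ranges": [[cfg.contig, start1 - 1, end1]],
                "type_restriction": ["any"],
                "notes": "synthetic mutated hotspot",
            }
        )
    for i, (start, dip_len, _d) in enumerate(cfg.dips):
        sites.append(
            {
                "site_id": f"HS_DIP_{i + 1}",
                "gene": _gene_of(start, cfg),
                "label": f"low-coverage site {i + 1}",
                "ranges": [[cfg.contig, start - 1, start + dip_len - 1 + 5]],
                "type_restriction": ["any"],
                "notes": "synthetic under-covered site",
            }
        )
    rng = rng_for(cfg.seed, "sites")
    truth_pos = sorted(t.variant.pos for t in truth)

    def clear_interval() -> tuple[int, int]:
        for _ in range(1000):
            s = int(rng.integers(100, cfg.reference_length - 100))
            e = s + int(rng.integers(5, 40))
            near_truth = any(s - 10 <= p <= e + 10 for p in truth_pos)
            in_dip = any(s <= d0 + dl and e >= d0 for d0, dl, _ in cfg.dips)
            if not near_truth and not in_dip:
                return s, e
        raise VariantError("could not place a clean wild-type site")

    for i in range(n_wildtype):
        s, e = clear_interval()
        sites.append(
            {
                "site_id": f"HS_WT_{i + 1}",
                "gene": _gene_of(s, cfg),
                "label": f"clean site {i + 1}",
                "ranges": [[cfg.contig, s - 1, e]],
                "type_restriction": ["any"],
                "notes": "synthetic well-covered wild-type site",
            }
        )

    sites_path = out_dir / "sites.json"
    sites_path.write_text(json.dumps({"version": "sim-1", "sites": sites}, indent=2) + "\n")

    rules = []
    if sites:
        first = sites[0]["site_id"]
        rules.append(
            {
                "rule_id": "R1_driver_found",
                "condition": f'state("{first}") == "MUTATED"',
                "recommendation_text": "Driver mutation detected; consider targeted therapy review.",
                "references": ["synthetic guideline 1"],
            }
        )
    if n_wildtype:
        wt = f"HS_WT_1"
        rules.append(
            {
                "rule_id": "R2_safe_exclusion",
                "condition": f'state("{wt}") == "WILDTYPE"',
                "recommendation_text": "Mutation safely excluded at the monitored site.",
                "references": ["synthetic guideline 2"],
            }
        )
    if cfg.dips:
        rules.append(
            {
                "rule_id": "R3_followup_coverage",
                "condition": f'state("HS_DIP_1") == "INSUFFICIENT"',
                "recommendation_text": "Coverage insufficient for exclusion; recommend re-sequencing.",
                "references": ["synthetic guideline 3"],
            }
        )
    rules_path = out_dir / "rules.json"
    rules_path.write_text(json.dumps({"rules": rules}, indent=2) + "\n")
    return sites_path, rules_path


# ---------------------------------------------------------------------------
# whole-dataset driver
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    """All generated artifacts of one synthetic sample, by path, plus the
    in-memory truth needed by tests and the acceptance evaluation."""

    config: SimulationConfig
    ref: ReferenceSequence
    truth: list[TruthVariant]
    fasta: Path
    target_bed: Path
    truth_vcf: Path
    truth_tsv: Path
    caller_vcfs: dict[str, Path]
    readcounts: Path
    coverage: Path
    manifest_v1: Path
    manifest_v2: Path
    flipped_key: str | None
    sites: Path
    rules: Path


def simulate_dataset(cfg: SimulationConfig, out_dir: str | Path) -> SimulatedDataset:
    """Generate every pipeline input under ``out_dir``; byte-reproducible
    for identical configurations."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref, bed, tracts = generate_reference(cfg)
    fasta = out_dir / "reference.fa"
    ref.to_fasta(str(fasta))
    bed_path = out_dir / "target.bed"
    bed_path.write_text(
        "".join(f"{c}\t{s}\t{e}\n" for c, s, e in bed)
    )

    truth = plant_truth_variants(ref, cfg, tracts)
    truth_vcf = out_dir / "truth.vcf"
    _write_vcf(
        truth_vcf, ref, [(t.variant.chrom, t.variant.pos, t.variant.ref, t.variant.alt, None) for t in truth]
    )
    truth_tsv = out_dir / "truth.tsv"
    with open(truth_tsv, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tvaf\tgene\teffect\n")
        for t in truth:
            v = t.variant
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{t.vaf:.4f}\t{t.gene}\t{t.effect}\n"
            )

    caller_vcfs = simulate_caller_outputs(truth, cfg.profiles, ref, cfg, out_dir / "callers")
    fp_keys = sorted(expected_fp_keys(caller_vcfs, truth, ref))
    readcounts, coverage = simulate_readcounts_and_coverage(
        truth, fp_keys, ref, cfg, out_dir
    )
    ann = simulate_annotations(truth, cfg, out_dir / "annotation")
    sites, rules = simulate_sites_and_rules(truth, cfg, out_dir)

    return SimulatedDataset(
        config=cfg,
        ref=ref,
        truth=truth,
        fasta=fasta,
        target_bed=bed_path,
        truth_vcf=truth_vcf,
        truth_tsv=truth_tsv,
        caller_vcfs=caller_vcfs,
        readcounts=readcounts,
        coverage=coverage,
        manifest_v1=ann["manifest_v1"],
        manifest_v2=ann["manifest_v2"],
        flipped_key=ann["flipped_key"],
        sites=sites,
        rules=rules,
    )
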