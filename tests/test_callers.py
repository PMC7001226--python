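"""VCF ingestion, multi-caller merging, readcount metrics, basic filter."""

import itertools

import pytest

from helpers import enumerate_equivalents
from varan.callers import (
    BasicFilterConfig,
    CallerOutput,
    ReadcountRecord,
    attach_readcounts,
    basic_filter,
    integrate,
    read_caller_vcf,
    read_readcount_tsv,
    supporting_allele_key,
    write_table_vcf,
)
from varan.variants import (
    Variant,
    VariantError,
    VariantRow,
    VariantTable,
    normalize_variant,
    variant_key,
)


def _write_vcf(path, records, contig_len=120):
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID=chr1,length={contig_len}>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for chrom, pos, ref, alt, filt in records:
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t50\t{filt}\t.")
    path.write_text("\n".join(lines) + "\n")
    return str(path)


class TestReadCallerVcf:
    def test_pass_snv(self, tmp_path, spec_reference):
        p = _write_vcf(tmp_path / "a.vcf", [("chr1", 100, "G", "T", "PASS")])
        out = read_caller_vcf(p, "gatk", spec_reference)
        assert len(out.variants) == 1
        assert out.native[variant_key(out.variants[0])]["gatk.FILTER"] == "PASS"

    def test_denormalized_deletion_stored_canonically(self, tmp_path, spec_reference):
        p = _write_vcf(tmp_path / "a.vcf", [("chr1", 106, "ACA", "A", "PASS")])
        out = read_caller_vcf(p, "gatk", spec_reference)
        v = out.variants[0]
        assert (v.pos, v.ref, v.alt) == (100, "GCA", "G")

    def test_multiallelic_split(self, tmp_path, spec_reference):
        p = _write_vcf(tmp_path / "a.vcf", [("chr1", 100, "G", "A,T", "PASS")])
        out = read_caller_vcf(p, "gatk", spec_reference)
        assert len(out.variants) == 2

    def test_failed_filter_retained_but_flagged(self, tmp_path, spec_reference):
        p = _write_vcf(tmp_path / "a.vcf", [("chr1", 100, "G", "T", "q10")])
        out = read_caller_vcf(p, "gatk", spec_reference)
        assert len(out.variants) == 1
        key = variant_key(out.variants[0])
        assert out.native[key]["gatk.FILTER"] == "q10"

    def test_symbolic_and_star_alleles_dropped(self, tmp_path, spec_reference, caplog):
        p = _write_vcf(
            tmp_path / "a.vcf",
            [("chr1", 100, "G", "<DEL>", "PASS"), ("chr1", 103, "C", "*", "PASS"),
             ("chr1", 105, "C", "T", "PASS")],
        )
        out = read_caller_vcf(p, "gatk", spec_reference)
        assert [v.pos for v in out.variants] == [105]

    def test_unknown_contig_is_error(self, tmp_path, spec_reference):
        lines = [
            "##fileformat=VCFv4.2",
            "##contig=<ID=chr9,length=200>",
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
            "chr9\t5\t.\tA\tT\t50\tPASS\t.",
        ]
        p = tmp_path / "bad.vcf"
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(VariantError, match="contig"):
            read_caller_vcf(str(p), "gatk", spec_reference)


class TestIntegrate:
    def test_single_caller(self, spec_reference):
        vs = [Variant("chr1", p, spec_reference.base("chr1", p), a)
              for p, a in [(20, "T"), (40, "C"), (60, "G")]
              if spec_reference.base("chr1", p) != a]
        out = CallerOutput("gatk", vs)
        table = integrate([out], "S1")
        assert len(table) == len(vs)
        assert all(r.caller_count == 1 for r in table.rows)

    def test_equivalent_representations_collide(self, spec_reference):
        canonical = normalize_variant(Variant("chr1", 106, "ACA", "A"), spec_reference)
        equivalents = enumerate_equivalents(canonical, spec_reference)
        a = CallerOutput("gatk", [normalize_variant(equivalents[0], spec_reference)])
        b = CallerOutput("freebayes", [normalize_variant(equivalents[-1], spec_reference)])
        table = integrate([a, b], "S1")
        assert len(table) == 1
        assert table.rows[0].caller_count == 2

    def test_count_over_eight_callers(self, spec_reference):
        v = Variant("chr1", 100, "G", "T")
        outputs = [
            CallerOutput(f"c{i}", [v] if i < 5 else [])
            for i in range(8)
        ]
        table = integrate(outputs, "S1")
        assert table.rows[0].caller_count == 5
        assert sorted(table.rows[0].caller_flags) == sorted(f"c{i}" for i in range(8))

    def test_permutation_invariance(self, spec_reference):
        v1 = Variant("chr1", 100, "G", "T")
        v2 = Variant("chr1", 103, "C", "A")
        outputs = [
            CallerOutput("a", [v1]),
            CallerOutput("b", [v1, v2]),
            CallerOutput("c", [v2]),
        ]
        tables = [
            integrate(list(perm), "S1").to_dataframe()
            for perm in itertools.permutations(outputs)
        ]
        for frame in tables[1:]:
            assert frame.equals(tables[0])

    def test_duplicate_caller_id_rejected(self):
        v = Variant("chr1", 100, "G", "T")
        with pytest.raises(VariantError, match="duplicate"):
            integrate([CallerOutput("a", [v]), CallerOutput("a", [v])], "S1")

    def test_row_count_bounds(self, spec_reference):
        v1, v2, v3 = (Variant("chr1", p, "G" if spec_reference.base("chr1", p) == "G" else spec_reference.base("chr1", p), "T")
                      for p in (100, 102, 104))
        outputs = [CallerOutput("a", [v1, v2]), CallerOutput("b", [v2, v3])]
        table = integrate(outputs, "S1")
        assert max(2, 2) <= len(table) <= 4


class TestReadcounts:
    def test_vaf_arithmetic(self):
        rec = ReadcountRecord("chr1", 100, "G", 200, {"T": 20, "G": 180}, {"T": 31.0, "G": 33.0})
        table = VariantTable("S1", [VariantRow(variant=Variant("chr1", 100, "G", "T"))])
        out = attach_readcounts(table, [rec])
        row = out.rows[0]
        assert row.vaf == pytest.approx(0.10)
        assert row.depth == 200
        assert row.mean_base_quality == 31.0

    def test_zero_depth_flagged_vaf_zero(self):
        rec = ReadcountRecord("chr1", 100, "G", 0, {}, {})
        table = VariantTable("S1", [VariantRow(variant=Variant("chr1", 100, "G", "T"))])
        out = attach_readcounts(table, [rec])
        assert out.rows[0].vaf == 0.0

    def test_missing_record_gets_no_readcount_flag(self):
        table = VariantTable("S1", [VariantRow(variant=Variant("chr1", 100, "G", "T"))])
        out = attach_readcounts(table, [])
        assert out.rows[0].annotations["no_readcount"] == "1"
        assert out.rows[0].depth == 0

    def test_indel_allele_keys(self):
        ins = Variant("chr1", 10, "A", "AAG")
        dele = Variant("chr1", 10, "ACA", "A")
        assert supporting_allele_key(ins) == "+AG"
        assert supporting_allele_key(dele) == "-CA"
        rec = ReadcountRecord(
            "chr1", 10, "A", 100, {"+AG": 25, "A": 75}, {"+AG": 30.0, "A": 33.0}
        )
        table = VariantTable("S1", [VariantRow(variant=ins)])
        out = attach_readcounts(table, [rec])
        assert out.rows[0].vaf == pytest.approx(25 / 100)

    def test_tsv_round_trip(self, tmp_path):
        p = tmp_path / "rc.tsv"
        p.write_text(
            "# header\n"
            "chr1\t100\tG\t200\tG:178:33.10\tT:20:31.00\t+AG:2:28.50\n"
        )
        recs = read_readcount_tsv(str(p))
        assert recs[0].allele_counts == {"G": 178, "T": 20, "+AG": 2}
        assert recs[0].mean_base_quality["+AG"] == 28.5


def _quality_table():
    rows = []
    specs = [
        # depth, vaf, bq, n_callers
        (100, 0.10, 30.0, 3),
        (10, 0.10, 30.0, 2),   # fails depth
        (100, 0.005, 30.0, 8), # fails vaf
        (100, 0.10, 10.0, 1),  # fails bq
        (100, 0.10, 30.0, 1),
        (500, 0.40, 35.0, 8),
        (19, 0.009, 14.0, 1),  # fails everything
        (20, 0.01, 15.0, 1),   # exactly at the default minimums
        (100, 0.02, 30.0, 2),
        (50, 0.03, 22.0, 5),
    ]
    for i, (depth, vaf, bq, nc) in enumerate(specs):
        rows.append(
            VariantRow(
                variant=Variant("chr1", 10 + i * 5, "A", "G"),
                caller_flags={f"c{j}": j < nc for j in range(8)},
                depth=depth,
                vaf=vaf,
                mean_base_quality=bq,
            )
        )
    return VariantTable("S1", rows)


class TestBasicFilter:
    def test_all_zero_config_is_identity(self):
        t = _quality_table()
        out = basic_filter(t, BasicFilterConfig(0, 0, 0, 0))
        assert out.keys == t.keys

    def test_min_caller_count(self):
        rows = [
            VariantRow(
                variant=Variant("chr1", 10 + i, "A", "G"),
                caller_flags={f"c{j}": j < n for j in range(8)},
                depth=100, vaf=0.1, mean_base_quality=30,
            )
            for i, n in enumerate([1, 2, 8])
        ]
        t = VariantTable("S1", rows)
        out = basic_filter(t, BasicFilterConfig(min_caller_count=2))
        assert len(out) == 2

    def test_mixed_failures_match_enumeration(self):
        t = _quality_table()
        cfg = BasicFilterConfig()
        expected = [
            r.key
            for r in t.rows
            if r.depth >= cfg.min_depth
            and r.vaf >= cfg.min_vaf
            and r.mean_base_quality >= cfg.min_base_quality
            and r.caller_count >= cfg.min_caller_count
        ]
        out = basic_filter(t, cfg)
        assert out.keys == sorted(expected, key=lambda k: int(k.split(":")[1]))

    def test_boundary_values_are_inclusive(self):
        t = _quality_table()
        out = basic_filter(t, BasicFilterConfig())
        assert "chr1:45:A>G" in out.keys  # the exactly-at-minimums row

    def test_idempotent(self):
        t = _quality_table()
        cfg = BasicFilterConfig()
        once = basic_filter(t, cfg)
        twice = basic_filter(once, cfg)
        assert once.keys == twice.keys

    def test_negative_threshold_rejected(self):
        with pytest.raises(VariantError):
            BasicFilterConfig(min_depth=-1)


def test_table_vcf_export_reimports(tmp_path, spec_reference):
    rows = [
        VariantRow(
            variant=Variant("chr1", 100, "G", "T"),
            caller_flags={"a": True, "b": True},
            vaf=0.25, depth=400, mean_base_quality=33.0,
        )
    ]
    table = VariantTable("S1", rows)
    out = tmp_path / "merged.vcf"
    write_table_vcf(table, str(out), spec_reference)
    re_read = read_caller_vcf(str(out), "merged", spec_reference)
    assert [variant_key(v) for v in re_read.variants] == table.keys
    assert "CALLER_COUNT=2" in out.read_text()
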