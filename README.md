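# varan

Somatic variant analysis for targeted NGS panels: merge the output of many
variant callers into one canonically normalized table, score every variant
with a customizable JSON scoring scheme into **a**rtifact and
**p**olymorphism scores, classify curated hotspot mutation sites as
*mutated* / *insufficiently covered* / *wild type* using full-region
coverage, derive rule-based diagnostic recommendations into a structured
clinical report, and benchmark call sets against validated truth sets.

The intended users are bioinformaticians running deep targeted panels
(e.g. myeloid-malignancy diagnostics) who need an ensemble calling
strategy with a reproducible, auditable filtering step between raw caller
output and a clinical report.

## The method

**Normalization.** VCF permits many spellings of the same edit, especially
for indels in repeat tracts. Every incoming allele is rewritten to its
unique parsimonious, maximally left-aligned representation (trim shared
suffix, keep a single left anchor base for indels, shift left while the
edit commutes with the preceding reference base), so all equivalent
descriptions collide on one key `chrom:pos:ref>alt`. Merging, annotation
joins and truth-set matching all operate on that key.

**Ensemble integration.** Each caller's VCF is split per ALT allele,
normalized and merged into one table with per-caller presence flags.
Quality metrics — VAF, depth, mean base quality — come from a single
per-base readcount table shared by all callers, so VAF = (supporting-allele
count) / depth has one denominator everywhere. A basic quality filter
(defaults: depth ≥ 20, VAF ≥ 0.01, mean BQ ≥ 15, ≥ 1 caller) removes
obvious junk before scoring.

**Scoring (SSDL).** A scoring scheme is a JSON document: categories hold
entries; an entry has an artifact weight w_A ≥ 0 and/or a polymorphism
weight w_P ≥ 0 and a condition tree of AND/OR nodes over sandboxed boolean
expressions (`x("column")`, `th("threshold")`, `isEmpty`, `stringContains`,
comparisons, and/or/not — no host-language escape). For a variant row r,

    A(r) = Σ w_A(e) over fired active entries e,
    P(r) = Σ w_P(e) analogously,

and the row is classified *artifact* iff A ≥ artifact_cutoff,
*polymorphism* iff P ≥ polymorphism_cutoff (inclusive; both → both label;
neither → *pass*). Thresholds are declared with default/min/max so a
settings panel can be derived mechanically from the scheme
(`list_controls`). A default scheme covering the usual ensemble criteria
(caller count, dbSNP membership and PM flag, COSMIC occurrence, population
allele frequency, VAF, base quality) ships in
`src/varan/schemes/default_scheme.json`.

**Hotspot status.** Curated mutation sites (1 bp up to whole exons, with
optional mutation-type restrictions) are classified three-valued:
*MUTATED* if any overlapping, type-matching, non-synonymous, not-benign,
pass-classified variant exists; otherwise *WILDTYPE* only if **every** base
of the site reaches the minimum depth (default 100×); otherwise
*INSUFFICIENT* — absence of evidence is never called wild type over an
under-covered region. Diagnostic rules are boolean expressions over
`state(site_id)` with strict three-valued discipline (INSUFFICIENT
satisfies neither a MUTATED nor a WILDTYPE test).

**Evaluation.** Calls match truth by exact normalized key; sensitivity
= TP/(TP+FN) and PPV = TP/(TP+FP), rounded half-up to 4 decimals, with
zero denominators reported as not-available.

A fully seeded synthetic-data generator (`varan.simulate`) produces every
input the pipeline consumes — reference with repeat tracts, truth variants
with VAFs, eight caller VCFs with per-caller sensitivity/false-positive/
denormalization behavior, readcounts, coverage with dips, annotation
snapshots, site registry, rulebook — so the whole stack is testable
offline.

## Worked example

```sh
varan simulate --seed 3 --n-variants 40 --outdir sim
varan report \
  --ref sim/reference.fa \
  $(for f in sim/callers/*.vcf; do printf -- "--vcf %s=%s " "$(basename $f .vcf)" "$f"; done) \
  --readcounts sim/readcounts.tsv \
  --snapshot-manifest sim/annotation/snapshot_v1.json \
  --sites sim/sites.json --coverage sim/coverage.bedgraph \
  --rulebook sim/rules.json --sample-id SIM-001 --outdir run
varan evaluate --ref sim/reference.fa --calls sim/truth.vcf \
  --truth sim/truth.vcf --outdir run
```

The last command prints

```
tp=41 fp=0 fn=0 sensitivity=1.0000 ppv=1.0000
```

(a call set evaluated against itself is perfect, which checks the matching
arithmetic; the 41 = 40 requested truth variants plus one indel the
generator always plants inside a repeat tract). `run/report.json` is the
archival report; `run/report.md` is the human view. Its overview section
lists each hotspot site with its traffic-light state:

```
- [RED] HS_MUT_1: MUTATED (min depth 1343, 100.0% covered) — supporting: chr1:600:ATC>A
- [RED] HS_MUT_2: MUTATED (min depth 1380, 100.0% covered) — supporting: chr1:1580:C>T
- [RED] HS_MUT_3: MUTATED (min depth 1375, 100.0% covered) — supporting: chr1:1594:T>TC
- [YELLOW] HS_DIP_1: INSUFFICIENT (min depth 30, 33.3% covered)
- [YELLOW] HS_DIP_2: INSUFFICIENT (min depth 40, 16.7% covered)
- [GREEN] HS_WT_1: WILDTYPE (min depth 1382, 100.0% covered)
- [GREEN] HS_WT_2: WILDTYPE (min depth 1402, 100.0% covered)
- [GREEN] HS_WT_3: WILDTYPE (min depth 1366, 100.0% covered)
```

*MUTATED* means a reportable driver mutation was found in the site's
ranges; *INSUFFICIENT* means no mutation was found but part of the region
is below the wild-type depth threshold, so absence cannot be claimed;
*WILDTYPE* means no mutation and full coverage. The report's provenance
block records the pipeline version, scheme, threshold overrides, annotation
snapshot fingerprint, site-registry version and timestamp; two runs on the
same inputs are byte-identical apart from the timestamp.

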