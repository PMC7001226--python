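# Methods

This note documents the models, conventions and numerical choices behind
the package; it is the place where genuinely open design decisions are
recorded as the package's own choices.

## Variant normalization

Internal coordinates are 1-based inclusive (the VCF convention); every
BED-style input (target regions, site-registry ranges, coverage tracks) is
converted from 0-based half-open at its parser, never downstream. Contig
names are unified to the `chr`-prefixed dialect on ingest (`MT` → `chrM`);
sorting is natural (`chr1..chr22, chrX, chrY, chrM`, other contigs
lexicographic after).

The canonical representation is parsimonious and maximally left-aligned.
The algorithm is the standard iterative one: repeatedly truncate equal
last bases (keeping at least one base in an allele); whenever an allele
empties, prepend the reference base to the left of the window and move the
position down; finally strip shared leading bases, keeping one anchor for
indels. An indel that shifts against the start of a contig is re-anchored
on the right. The test suite checks this algorithm against a brute-force
oracle that enumerates, on short contigs, *every* (pos, ref, alt) whose
application yields the same alternate haplotype and picks the unique
minimal-length leftmost one; the two agree on 100% of generated cases, and
the operation is a fixed point of itself.

Symbolic alleles (`<DEL>`, breakends), spanning-deletion `*` alleles and
alleles containing N are dropped with a logged warning: the tool targets
SNVs and small indels only. Multi-nucleotide substitutions are kept whole
(caller intent is preserved; decomposition into SNVs is not performed).
Structural variants and large tandem duplications are out of scope.

## Ensemble integration and quality metrics

One merged table holds one row per unique normalized key with per-caller
boolean flags; the merge is a pure function of the *set* of caller
outputs (order-independent, verified by permutation tests). Caller-native
fields (FILTER status, QUAL) are carried as opaque string columns
`<caller>.<field>` so scoring rules can reference them; records failing a
caller's FILTER are kept and flagged, because filtering is the scoring
scheme's job, not the reader's.

VAF, depth and mean base quality are always taken from a single per-base
readcount table (`allele:count:mean_bq` triplets at each position), never
from caller-reported AD/AF fields — one denominator for all callers.
Insertion/deletion supporting alleles use the `+inserted`/`-deleted` key
convention of per-base readcount tools, looked up at the normalized anchor
position. A row with no readcount record receives depth 0, VAF 0, BQ 0 and
a `no_readcount` flag rather than failing.

The basic pre-scoring filter defaults to depth ≥ 20, VAF ≥ 0.01, mean base
quality ≥ 15, caller count ≥ 1. These are deliberately permissive — the
filter exists to remove unscoreable junk, and every threshold is
configurable.

## The scoring scheme language

Schemes are JSON with fixed field names (`categories` → `entries` →
`condition`; `thresholds`; `cutoffs`). The expression language is a
deliberately tiny sandbox rather than host-language snippets: embedding a
general-purpose language in a clinical filter is neither safe nor
portable. Grammar: literals (numbers incl. negative, quoted strings,
true/false), `x(name)`, `th(name)`, `isEmpty(s)`,
`stringContains(h, n)`, comparison operators, `and`/`or`/`not`,
parentheses. No assignment, loops or calls beyond these.

Semantics chosen for missing data: `x()` returns the raw cell string and a
missing column is the empty string, so `isEmpty` is the designated
missingness test. Ordering comparisons coerce both sides to numbers; if
either side does not parse, the comparison is **false** and a per-row
diagnostic is recorded — missing evidence never fires a rule. Equality
compares numerically when both sides parse and as strings otherwise.
Column references are checked against the table's column registry before
any row is evaluated, so a typo in a scheme fails at scheme-application
time, not silently per row.

An entry fires at most once however large its condition tree; active
entries add their weights (restricted to ≥ 0) to the artifact and/or
polymorphism sums. Cutoffs default to 1.0/1.0 and are inclusive, so a
single weight-1 rule suffices to classify. The shipped default scheme
implements the classic ensemble-filtering criteria — minimum caller count,
database membership without a clinical (PM) flag at elevated population
frequency and without notable somatic-database occurrence, benign clinical
significance, minimum VAF and base quality — with weight 1 per rule. The
exact weights of published filtering schemes are not reproduced here; the
engine loads any scheme document, and the default is a reasonable,
replaceable baseline.

Correctness of the evaluator is established by a dual route: random
schemes are generated *structurally*, rendered to JSON, and evaluated both
by the production parser+evaluator and directly on the structure by an
independent interpreter; 1,000 random scheme × row pairs must agree
exactly.

## Annotation snapshots

Annotation sources are flat files (TSV keyed by chrom/pos/ref/alt, or VCF
whose INFO keys become columns), normalized on load (duplicate keys after
normalization: first wins, warning logged) and joined onto the table at
retrieval time with `source.` column prefixes. The snapshot fingerprint is
a SHA-256 over the sorted `source:version` pairs — order-invariant,
sensitive to any version change — and goes into report provenance, so the
annotation state behind any report is identifiable. Missingness is the
empty string everywhere; allele frequencies are stored as decimal strings
and coerced only inside scheme comparisons.

## Hotspot three-state classification

A site is a set of ranges with a type restriction (`SNV`, `INS`, `DEL`,
`MNV`, `frameshift_only`, `any`). Overlap rules: a substitution overlaps
where a changed reference base lies; a deletion overlaps where a deleted
base lies; an insertion overlaps at its anchor base or the base after —
insertions in repeat contexts have ambiguous placement, and this rule
keeps a 4 bp frameshift insertion "around" a known position inside its
site. `frameshift_only` is tested via the functional-effect annotation
containing "frameshift"; protein-level recomputation is out of scope.

Relevance requires all of: range overlap, type match, non-synonymous
effect, no clinical-significance annotation containing "benign"
(case-insensitive; absence of the column counts as not-benign —
conservative toward reporting; an empty effect string likewise counts as
eligible), and a `pass` classification after both the basic filter and
the scoring scheme.

States: MUTATED whenever a relevant variant exists, regardless of
coverage; else WILDTYPE only when every base of every range has depth ≥
the wild-type threshold (default 100 reads — the usual exclusion depth for
deep panels; configurable per run); else INSUFFICIENT. Classification is
exhaustive and exclusive, monotone in coverage, and reacts to scheme
overrides (reclassifying a supporting variant as artifact can demote a
site from MUTATED).

## Rules and reports

Diagnostic rules reuse the expression sandbox plus `state(site_id)` and
are validated against the site registry at load. Logic is strictly
three-valued through explicit equality tests: `INSUFFICIENT` satisfies
neither `== "MUTATED"` nor `== "WILDTYPE"`, so no recommendation can rest
on an unsafe "absence means wild type" inference.

The report document is coarse-to-fine: sample metadata, color-coded site
overview, fired recommendations, per-site detail, provenance. Provenance
(pipeline version, scheme name+version, threshold overrides, annotation
snapshot fingerprint, site-registry version, timestamp) is mandatory;
building a report without it is an error. JSON rendering is lossless
(parse-back equality); two runs over identical inputs are byte-identical
except the timestamp, which is the archival guarantee: PDF rendering and
a report archive service are intentionally out of scope, JSON is the
archival format and markdown the human view.

## Evaluation arithmetic

Matching is exact normalized-key equality — normalization, not fuzzy
position windows, reconciles representation differences (a caller's
right-shifted indel counts as a true positive, verified with the
equivalence oracle). Optional region restriction applies to both sides
before counting. Sensitivity and PPV are rounded half-up to 4 decimals
(this reproduces every published value recomputed in the acceptance
tests); zero denominators yield not-available, never zero.

## The synthetic-data generator

The generator emulates a deep targeted amplicon panel of the kind used in
myeloid diagnostics, with defaults chosen as that study condition:

| parameter | default | rationale |
|---|---|---|
| target size | 42 kbp, one contig | typical small myeloid panel |
| truth variants | 500 | enough for stable rate estimates |
| truth VAFs | Uniform(0.05, 0.60) | somatic range incl. subclones |
| coverage | floor 300 + Poisson(1150) ≈ 1450× mean | deep amplicon panel |
| dip windows | 10–25 bp at 30–40× | localized amplicon dropouts |
| callers | 8 profiles, sensitivity 0.70–0.95, ~0.4–0.6 FP/kbp, denormalization probability 0–0.4 | ensembles of callers produce highly differing lists |
| FP noise VAF | 0.03 | low-level noise at false-call sites |
| dbSNP membership | 25% of truth (half PM-flagged), population AF Uniform(0.0005, 0.05) | mix of rare and common look-alikes |
| COSMIC-like occurrence | 30% of truth, counts 1–60 | known somatic recurrence |
| benign clinical flag | 4% of truth | occasional benign annotations |

Each output file draws from its own pseudo-random stream derived from
(seed, file role), so adding a caller perturbs no other file and the whole
dataset is byte-reproducible under a fixed configuration. False-positive
calls are SNVs placed uniformly outside the neighborhoods of truth
variants, which keeps true- and false-call statistics analytically
separable; truth variants are likewise kept off repeat tracts (except one
deliberately planted tract indel per dataset to exercise normalization)
and off coverage-dip windows — a biologically validated variant sitting on
a dead amplicon would confound the coverage analysis. Simulated "sloppy"
callers emit haplotype-equivalent right-shifted and/or flank-padded
representations with a per-caller probability.

What the generator does **not** emulate: read-level errors (no FASTQ/BAM),
strand bias, mapping artifacts, caller-specific systematic error modes, or
correlated failures between callers (detections are independent per
caller). Passing tests therefore demonstrate the correctness of the
integration/scoring/classification machinery under a clean error model,
not the field performance of any particular caller ensemble on real data.

## Problem sizes and statistical checks

The end-to-end check runs the default conditions (500 truth variants,
eight callers, default filter and scheme) and compares measured
sensitivity/PPV with their analytic expectations: a truth variant is
expected to be reported iff at least two callers detect it (the default
scheme's caller-count rule) and no database rule excludes it; detection
counts follow a Poisson-binomial over caller sensitivities, and the test
asserts the measurement inside the central 99.7% interval. Surviving false
positives require two callers to collide on the same position *and*
allele, an event with mean well below one per dataset; the test bounds it
by the corresponding Poisson quantile. The normalization oracle runs on
contigs ≤ 30 bp where exhaustive enumeration is feasible; scheme
equivalence uses 1,000 random scheme/row pairs; the rulebook check
enumerates all 3⁴ site-state combinations over four sites.

## Known limitations

- Exact-key matching only; a truth set using a different reference build
  or non-equivalent representation conventions will not match.
- Scheme weights are restricted to non-negative values; "rescue" rules
  must be encoded as conjunctive exceptions inside a penalty rule rather
  than as negative weights.
- The hotspot module does not map protein coordinates (HGVS p.) or
  transcripts; sites are genomic ranges curated upstream.
- Rules see site states only, not variant-level features such as VAF.
- Per-base coverage tracks are held in memory; the design targets
  targeted panels (tens of kbp), not exomes.
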