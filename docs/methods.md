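# Methods

## The analysis problem

Severe adolescent idiopathic scoliosis (AIS; Cobb angle > 40°) is rare
enough that cohort studies collect on the order of ten patients, too few
for association testing. The tractable question is prioritization:
given whole-exome variant calls annotated with population frequencies
and pathogenicity evidence, which rare variants and genes deserve
follow-up? `scoliovar` implements that prioritization cascade for an
11-patient-scale cohort of heterozygous nonsynonymous SNVs on GRCh38,
consuming already-annotated tables (ANNOVAR-style TSV or annotated VCF);
upstream read processing, alignment, calling and annotation are out of
scope, and CADD/REVEL/ClinVar values are consumed, never computed.

## Filter cascade

1. **Consequence.** Keep rows with at least one allowed transcript
   consequence (default `nonsynonymous SNV` / `missense`). A row may
   carry several transcript annotations; it passes if *any* is allowed
   (the conservative generalization when only one transcript is
   reported per variant).
2. **Rarity.** Keep variants whose minor-allele frequency is at/below
   `maf_threshold` (default 0.01) in *every* consulted panel: Taiwan
   Biobank, 1000 Genomes EAS, gnomAD EAS, ExAC EAS. Two deliberate
   readings are exposed:
   - *Inclusive by default* (`<= 0.01`). The study's text says "<0.01",
     but its printed dual-evidence table admits a variant with a panel
     frequency of exactly 0.01; only the inclusive comparison is
     consistent with the printed rows, so it is the default and the
     strict mode is an option (`threshold_inclusive=False`). A
     regression test documents that exactly one printed row separates
     the two modes.
   - *Absent counts as rare.* A `-` cell means the variant is
     unobserved in that panel, not frequency zero; printed rows with
     absent cells passed the filter. Absence is represented as `None`
     end-to-end and never compares equal to 0.0.
   - *Conjunction over panels* (`require_all_sources=True`), matching
     the enumerated list of panels; the disjunction is available but
     non-default.

## Dual-track pathogenicity classification

Two independent evidence tracks, combined by union and intersection:

- **ClinVar track**: the normalized clinical-significance label
  (lowercased, underscores to spaces, compound `/` labels kept whole)
  is in the whitelist {association, conflicting interpretations of
  pathogenicity, likely pathogenic, pathogenic, pathogenic/likely
  pathogenic}. Matching is on the full label, never substrings, so
  `benign/likely benign` cannot match a `likely pathogenic` fragment.
  All review statuses are accepted; multi-record variants must be
  pre-aggregated to one label upstream.
- **Score track**: CADD Phred strictly above 20 (top 1% deleterious)
  AND REVEL at or above 0.75 (high-specificity missense cutoff). The
  asymmetry (strict vs inclusive) mirrors the thresholds as stated;
  both printed boundary rows (CADD 20.3, REVEL 0.757) are consistent
  with it. A missing score fails the conjunction: absence of evidence
  is never pathogenic evidence.

The inclusion–exclusion identity |A∪B| + |A∩B| = |A| + |B| is asserted
structurally and property-tested; raising either score threshold or
shrinking the whitelist can only shrink the corresponding track.

## Burden, sharing, profiles, candidates

- **Gene burden** counts qualifying variants per annotated gene symbol
  and track. Burden is evidence, not a partition: a variant on two
  overlapping genes would count once per gene. Ordering is any-track
  count descending, ties broken lexicographically; symbol-less variants
  go to an `UNANNOTATED` bucket with a warning.
- **Sharing** lists, per pathogenic variant, the patients carrying at
  least one alternative allele (all heterozygous in this design), with
  a carrier-count histogram.
- **Patient profiles** report each patient's any-track variants plus a
  relaxed *rescue* re-screen — rare variants satisfying at least one
  single criterion component in isolation (whitelisted label OR CADD
  above threshold OR REVEL at/above threshold) — for patients in whom
  the strict cascade finds nothing.
- **Candidate genes** are, by default, the union of genes carrying any
  any-track pathogenic variant and literature-panel genes carrying any
  rare variant in the cohort. The composition rule was genuinely open;
  the union is the closest reading of "genes that include pathogenic
  rare variants and AIS-related genes identified in the sequencing
  data", and `mode="pathogenic_only"` switches it off.
- The packaged 56-gene AIS literature panel is a synthetic stand-in
  reconstruction (see the file header): the ten panel genes actually
  printed with cohort variants, plus 46 literature AIS genes.

## Over-representation analysis

For a query of n candidate genes restricted to an N-gene background and
a set of K genes overlapping the query in k, significance is the
hypergeometric upper tail P(X ≥ k), X ~ Hypergeometric(N, K, n)
(`scipy.stats.hypergeom.sf`; tests verify it against exact rational
enumeration for all parameters with N ≤ 25). Per collection, p-values
are BH step-up adjusted, q_i = min_{j≥i} p_(j)·m/j capped at 1, with
m = the number of sets actually tested after the size window
(default 5–2000). `bh_adjust` is written in-package because it must
support m larger than the number of supplied p-values (adjusting a
printed top-hit subset against the full test count); it is
cross-checked against `statsmodels` when m equals the vector length and
against a brute-force double loop on random vectors. Significance is
q < 0.05. The background defaults to the collection's member union, is
configurable, and is always reported in the output header, since no
universal choice exists. Ties in p are broken by set name for
deterministic output. GO-DAG redundancy reduction and ranked (GSEA)
statistics are out of scope.

**Reconstructing a printed BH table.** Published enrichment tables
print p and q rounded to ~3 significant figures but not m. Because both
columns are roundings, m is recovered by interval search: m is
consistent iff, for every row, the step-up q interval induced by the p
rounding interval overlaps the printed q's rounding interval. On the
four-row pathway table shipped as a fixture this yields a unique
m = 326; recomputed q-values then agree with the printed ones to one
unit in the last printed digit (exact 3-figure equality is impossible
for one row from the rounded p alone — its printed q was computed from
the unrounded p).

An optional two-column human→mouse symbol mapping supports
Mammalian-Phenotype-style collections; unmapped symbols are reported,
and many-to-one mappings collapse by set semantics.

## Synthetic cohort generator

The generator emulates the statistical shape the cascade assumes —
an 11-patient cohort (8 female), heterozygous-only genotypes, four
panel frequencies with per-panel missingness, ClinVar label dialects
with underscores, and planted structure at the scale the study reports:
87 ClinVar-track / 136 score-track / 7 dual-evidence variants (union
216; 76 and 130 distinct genes), 213 singletons plus one 4-carrier and
two 2-carrier shared variants, an 8-variant and a 3-variant gene
burden, 11 rare variants in 10 literature-panel genes, and exactly 206
candidate genes, of which 200 map to mouse symbols. These totals are
fixed counts in the configuration — they are the study conditions, not
free dials; the random seed controls only placement (loci, carriers)
and annotation draws. Non-qualifying filler (synonymous, common, and
benign rare variants) exercises each filter. Plants draw annotations
strictly inside their track's acceptance region (CADD in [22, 38],
REVEL in [0.78, 0.98], frequencies ≤ 0.009, benign draws failing at
least one criterion), so planted-truth recovery is exact and
deterministic; boundary draws (e.g. CADD exactly 20) are possible only
by explicit construction and are reported as intentionally unrecovered.
A companion builder emits a gene-set collection with one planted
(K=83, k=9) enriched set among 325 uniform decoy sets on a 12000-gene
universe — a geometry at which the planted overlap is significant at
q < 0.05 after BH over the 326 tests, as in the study's pathway table —
plus an ortholog mapping leaving a configurable 6 genes unmapped.

What the generator does *not* emulate: read-level data, linkage or
haplotype structure, relatedness, annotation errors, multi-allelic
sites or indels (SNV-only, matching the analysis scope), or realistic
joint frequency spectra. Passing recovery tests therefore demonstrates
correctness of the deterministic cascade on data with the assumed
marginal structure, not robustness to real-data annotation noise.

## Determinism and numerics

One seeded `numpy` Generator per run with a fixed draw order makes
generated cohorts byte-identical across platforms; the pipeline itself
is deterministic, and re-running on identical inputs reproduces every
output file byte-for-byte. Variant identity is `(chrom, pos, ref,
alt)`; gene symbols are annotation and matched case-sensitively by
default (an uppercase-normalization flag exists because human and mouse
conventions differ). Coordinates are 1-based closed GRCh38 with no
liftover. Frequencies/scores round-trip exactly through the TSV dialect
and at float32 precision through VCF INFO fields. The hypergeometric
tail is returned exactly as 1.0 at k = 0 regardless of floating-point
cancellation.

## Problem sizes used by tests and the acceptance script

Worked-example checks run on the encoded 18-variant tables. Synthetic
checks use the default 377-variant cohort, the 326-set collection and a
1000-replicate global-null simulation (vectorized; the whole acceptance
script completes in well under a minute). The exact-oracle sweep covers
every hypergeometric parameter combination with N ≤ 25 and 1000 random
BH vectors. These sizes are the package's own choices for desk-scale,
fully reproducible verification.

## Known limitations

- The ClinVar track trusts the supplied label; no star-rating weights,
  no ACMG criteria, no adjudication of conflicting records.
- Burden counts are raw; no calibrated burden test (SKAT/CMC) is
  attempted at n = 11.
- ORA results depend on the supplied collection and background; the
  package makes both explicit rather than claiming any database
  version's exact term list.
- The candidate-gene union rule is one defensible reading of an
  under-specified selection criterion; the alternative is exposed as
  configuration.
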