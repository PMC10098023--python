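# Methods

## Data model and conventions

Coordinates are 1-based inclusive throughout (VCF convention); BED input is
converted on read (0-based half-open). Contig dialects ("chr1" vs "1") are
reconciled by prefix-stripped comparison, since panel definitions and VCFs
commonly mix Ensembl and UCSC naming. Genotypes are alternate-allele dosage
codes per (sample, biallelic site): 0/1/2 plus a missing sentinel.
Half-calls (`./1`) are treated as missing — the conservative choice for
every denominator downstream. Phasing is ignored; only dosage enters any
statistic. Records with a non-PASS FILTER are dropped by default (variant
quality recalibration is assumed applied upstream) with a flag to retain
them. Multiallelic records are decomposed into one biallelic child per
alternate allele; each child's code counts copies of that allele only, so
alt-allele copies are conserved and samples missing at the parent stay
missing in every child.

Panel intervals are grown by a configurable flank (default 300 bp, matching
standard practice of including proximal regulatory sequence) and then
merged per chromosome, including book-ended neighbours. Whether
overlapping transcripts should merge after extension was a genuinely open
choice; we merge, because downstream subsetting only asks whether a
position is covered, and merging makes that test unambiguous and idempotent.

## Quality-control metrics

Per-sample counts are over the variant sites the sample carries (dosage ≥
1), not allele copies — the standard per-individual exome-QC framing.
Ti/Tv is computed over carried biallelic SNVs (transitions A↔G, C↔T);
Het/non-ref-Hom is heterozygous over homozygous-alternate genotype counts.
Zero denominators yield an explicit undefined value rather than an error.
Both an all-sites and a dbSNP-known-only (rsID-bearing) mode are provided,
since published per-sample Ti/Tv figures are often restricted to known
variants. Per-chromosome scope partitions the exome-wide counts exactly.

Cohort comparisons use Welch's unequal-variance two-sided t-test (the
safer default when only "t-test" is specified); zero-variance degenerate
inputs are guarded (equal constants → p = 1, distinct constants → p → 0).
Frequency concordance against previously published estimates is an
ordinary least-squares fit on the rsID intersection (≥ 3 shared sites
required), reporting r, p, slope, intercept and n.

Under Hardy–Weinberg sampling the expected Het/non-ref-Hom ratio at
frequency p is 2(1−p)/p, and the expected number of carried sites per
sample is Σ_j (1 − (1−p_j)²); both are used as closed-form oracles in the
test suite.

## Allele-frequency contrasts

Cohort frequencies are alt-count / called-alleles with missing genotypes
excluded from both terms, so per-site denominators vary (a fully-called
258-sample cohort gives 516 alleles; one missing genotype gives 514). When
only a printed frequency is available, `infer_allele_count` searches even
denominators for an integer count whose exact fraction reprints as the
given value at its own precision; published tables mix rounding and
truncation (the same 34/514 site appears as both 0.06615 and 0.06614), so
both are accepted, and among matches the largest denominator (fewest
assumed missing genotypes) wins.

Reference counts come from round(freq × 2N): reference-panel frequencies
are exact rationals of allele counts, so rounding reconstructs them.
Variants absent from a population are skipped for it — absence means no
data, not frequency zero.

`fisher_exact_2x2` computes the standard two-sided exact p-value: the sum
of probabilities of all tables with the observed margins whose
hypergeometric probability does not exceed the observed one. For totals
≤ 500 the enumeration uses exact integer arithmetic (`math.comb`), which
makes ties and near-ties exact rather than float-dependent; larger tables
delegate to scipy's C implementation of the same definition. The test
suite checks the exact path against an independent brute-force rational
enumeration on every table with margins ≤ 30, and both paths against scipy.

The Bonferroni family size m defaults to the number of variants tested
against a given population; a global (variants × populations) family and
an explicit override are available. The per-population default is what
reproduces the published per-cell significance stars: re-deriving counts
from the printed cohort and reference frequencies reproduces the star
status of every populated cell in the packaged result tables (44
pharmacogenomic, 39 consensus-risk, 29 prior-report cells) at m = 2174,
the published number of variants tested. The
reproduction report lists every cell so a failure is visible, never
silently passed.

## Variant-of-interest selection

The consensus rule scores each missense variant against five criteria —
SIFT < 0.05 (or an explicit deleterious call), PolyPhen2 ∈ {P, D},
REVEL > 0.5, ClinPred > 0.5, and a lipid-related phenotype in ClinVar or
the GWAS catalog — and qualifies it with ≥ `min_sources` (default 3)
criteria and ≥ `min_alt_count` (default 2) alternate copies. Missing
scores count as criterion-false: the rule counts satisfied criteria, not
available ones. The phenotype criterion uses a configurable keyword
lexicon (cholesterol, triglycerid-, lipoprotein-, hyperlipid-, dyslipid-,
HDL, LDL, sitosterolemia, LCAT, apolipoprotein, …) because no closed
definition of "lipid-related" exists; the default lexicon covers every
phenotype string in the packaged tables without matching the
pharmacogenomic distractors.

VEP impact classing uses the embedded Sequence Ontology severity table
(Ensembl ordering) with the variant's most severe term deciding its class;
unknown terms degrade to MODIFIER with a warning (strict mode raises).
Each variant contributes to exactly one impact class, which preserves the
het + hom = total identity in burden summaries. Pharmacogenomic/protective
flags derive from ClinVar significance categories plus trait-string
keywords (response/statin/warfarin; protect-, including a published
"potection" typo). Prior-report matching intersects cohort rsIDs with a
curated list (the packaged transcription, user-replaceable). The VOI union
deduplicates by rsID, falling back to a position+alleles key for novel
variants, and records every nominating route per variant.

## Synthetic cohorts

The generator emulates the study conditions the pipeline assumes: 250
diploid samples (the motivating cohorts pooled 258), ~5,000 panel sites,
site-level Ti/Tv odds 2.0 (transcriptome-wide calling sits below the ~3.0
coding-only standard), indel and multiallelic site fractions 5.4% and 2.9%
(the published panel's composition), alternate-allele frequencies from
Beta(0.3, 3) — rare-skewed, as in the published tables where most
frequencies are below 0.1 — 0.5% independent missingness, and 98% of sites
carrying an rsID. Genotypes are two i.i.d. allele draws per sample per
site (Hardy–Weinberg); annotation scores are drawn inside or outside each
criterion's qualifying region according to a designed risk subset;
reference panels perturb the cohort truth on the logit scale
(N(0, divergence), default 0.5) with an optional designed
differential-frequency set shifted by a fixed |Δp| on the probability
scale. One global seed drives independent per-stage substreams, so outputs
are byte-identical across runs and stages can be regenerated in isolation.

Two deliberate limits. The Ti/Tv target is exact for biallelic SNVs; a
multiallelic SNV site cannot carry two transition alternates, so its
allele mix is slightly transversion-enriched — frequency-contrast and
Ti/Tv-convergence experiments therefore use biallelic-only configurations.
And because multiallelic children share their parent's rsID, per-rsID
keyed joins (reference panels, annotation tables) are ambiguous for them;
the reference-panel stage refuses duplicate keys rather than silently
collapsing them.

What the simulator does not model: linkage disequilibrium, demography,
relatedness, genotyping error correlated with genotype, and
transcript-level annotation multiplicity. Passing tests therefore
demonstrate the correctness of the statistical machinery under the stated
sampling model, not robustness to the correlation structure of real
cohorts.

## Ancestry screen

AIM genotypes from one or more labeled cohorts are merged by rsID; any AIM
with a missing genotype anywhere in the merged sample set is dropped
(complete-case rule) and reported. PCA runs on the alternate-allele count
matrix with column mean-centering only — no unit-variance scaling, since
the inputs are on a common 0–2 scale — and pooled centering across cohort
and reference samples (projection onto reference-only axes is the main
alternative; pooling is the simpler choice and matches how the combined
matrix is assembled). Component signs are fixed by forcing each
component's largest-magnitude loading positive, for reproducible plots.
Variance fractions are validated against a brute-force covariance
eigendecomposition. Per-population allele-frequency export (alt copies /
2 × population size) feeds external tree/admixture software; model-based
admixture inference is out of scope.

## Problem sizes and tolerances in the test suite

Simulation-backed tests use 250 samples × 5,000 sites for the
frequency-contrast power/size experiment (250 designed differential sites,
|Δp| = 0.3, one 2,504-sample reference; power must reach 0.95 and the
false-positive fraction must stay within the Bonferroni-corrected level),
40 samples × 10,000 sites for Ti/Tv convergence (3 delta-method standard
errors around the target), and 400-sample configurations for the
Hardy–Weinberg goodness-of-fit check (≤ 1% of common sites rejected at
α = 0.001). The exact-Fisher oracle sweep is exhaustive over all 2×2
tables with margins ≤ 30 at 1e-12 absolute tolerance. Fixed seeds make
every stochastic assertion reproducible.

## Known limitations

Published cohort-scale figures that depend on the access-controlled
genomes (total panel variant counts, mean per-sample Ti/Tv 2.33,
Het/non-ref-Hom 1.66, ~137,593 SNVs per sample, burden means, PCA variance
percentages) are context, not test targets. The published LOW-impact
burden means are internally inconsistent at the second decimal (34.9 +
21.36 = 56.26 ≠ 56.22, and 0.82 + 0.43 ≠ 1.03 for HIGH); this package
treats total = het + hom as normative and does not attempt to reproduce
those printed means. Annotation is consumed from files — there is no live
VEP/ClinVar/GWAS querying — and the consensus scores themselves (SIFT,
PolyPhen2, REVEL, ClinPred) are inputs, never re-implemented.
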