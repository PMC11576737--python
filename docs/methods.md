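# Methods

This note documents the models, rules and numerical choices behind
`sftriage`, and what the synthetic cohorts do and do not establish about
behavior on real data.

## Variant representation

All coordinates are 1-based and fully closed, including the gene region
map (documented explicitly to avoid BED half-open confusion). Multi-
allelic sites are decomposed into one biallelic record per ALT allele;
a sample's dosage for an ALT is its count of that allele, other ALT
alleles counting as reference. After decomposition the allele number AN
at each record counts all called alleles at the original site, so MAF
stays comparable across the decomposed records (the joint-calling
convention). Genotypes containing any missing allele are treated as
fully missing and excluded from both AC and AN; how half-calls such as
`./1` should be counted is a convention, and this is the one we chose.
Haploid calls are doubled with a warning — no X-linked dosage logic is
otherwise exercised. Spanning-deletion alleles (`*`) are dropped and
logged; records with AN = 0 are dropped and logged.

Normalization trims shared trailing bases (extending left from the
reference when an allele would empty) and then shared leading bases down
to a single anchor, which left-aligns indels across repeat runs. Left
extension needs a reference oracle (a FASTA); without one, trimming is
still performed but left-alignment is skipped with a warning. The
operation is idempotent and is tested against an independent
exhaustive-equivalence search that enumerates every bounded-length
representation reproducing the same alternate haplotype and picks the
shortest, leftmost one.

Cohort MAF is folded onto [0, 0.5] as `min(AC/AN, 1 − AC/AN)` so the
frequency filters are orientation-free.

## Transcript selection

Effect predictions are per transcript; classification uses exactly one.
The MANE transcript wins when flagged (two MANE flags for one variant is
a data error). Otherwise the transcript whose most severe consequence
term ranks best wins; the severity table is a frozen copy of the
published Ensembl consequence ordering shipped as package data, so
results cannot drift with an external release, and an unknown term is an
error rather than silently least-severe. Rank ties go to the longest
transcript; whether "longest" means CDS or full transcript length is
delegated to the annotation producer, which supplies the single
`transcript_length` column. Remaining ties break on the
lexicographically smallest transcript id purely for determinism.

## The decision tree

Thresholds (a frozen dataclass, overridable per run and echoed in every
report): global cohort-MAF gate 2%, rarity cut 0.1% (cohort **and**
gnomAD), REVEL floor 0.7, minimum 2 carriers for the rare-missense
lists, minimum 2 ClinVar review stars for P2. Every comparison is strict
in the stated direction ("< 2%", "< 0.1%", "> 0.7", "more than one");
a cohort MAF of exactly 0.1% therefore fails rarity, and REVEL exactly
0.7 fails the floor.

Rule order and the decisions taken where the design was genuinely open:

1. Global MAF gate, then ClinVar B/LB rejection.
2. A ClinVar P/LP variant with an HGMD entry other than DM has
   conflicting database assessments. The conflict excludes it from both
   P1 and P2 (P2 is defined by absence from HGMD) and is terminal: such
   variants are not forwarded to the LP/pVUS branches (those require
   VUS/conflicting/novel status) and end unclassified.
3. P1 requires ClinVar P/LP + HGMD DM; P2 requires ClinVar P/LP,
   no HGMD entry, ≥ 2 stars.
4. LP1: a loss-of-function consequence (nonsense, frameshift, splice
   acceptor/donor, inframe insertion/deletion), PVS1 Very Strong, VEP
   impact HIGH, rare in cohort and gnomAD, in a gene where LOF is an
   established disease mechanism. The LOF-mechanism flag is a per-gene
   boolean column in the shipped catalog — data, not code — defaulting
   to true except for genes whose actionable mechanism is
   gain-of-function or dominant-negative (e.g. RYR1, CACNA1S, TTR, the
   non-MYBPC3 sarcomeric HCM genes, the calmodulins).
5. LP2/pVUS: missense, ClinVar VUS/conflicting or novel, rare in cohort
   and gnomAD, more than one carrier (distinct participants with dosage
   ≥ 1, not allele count), REVEL > 0.7, cancer or cardiovascular gene,
   and cohort disease evidence. The external combinatory verdict then
   splits LP2 (P/LP) from pVUS (anything else).

"Novel" means absent from all four of dbSNP, gnomAD, ClinVar and HGMD;
a variant absent from ClinVar but present in dbSNP is neither reported-
VUS nor novel and stays unclassified. A gnomAD frequency that is absent
passes the gnomAD rarity filter — a variant unseen in gnomAD is rare
there, and the alternative would exclude all novel variants, which the
rare-missense lists explicitly include. The global 2% gate uses cohort
MAF only. Every rule that fires is recorded in an ordered reason trail.

## Cohort evidence and association

Disease evidence per participant is the logical OR of questionnaire/
laboratory components: CVD (abnormal ECG, self-reported heart disease,
revascularization, first-degree family history), cancer (personal or
parental history, tumor surgery, screening below the sex-specific
recommended age), and FH (hypercholesterolemia diagnosis, or LDL at or
above 4.9 mmol/L — the threshold is configurable, the boundary is
inclusive and documented). Familial-hypercholesterolemia genes map to
the FH (lipid) stream, other cardiovascular genes to CVD, cancer genes
to cancer.

A variant qualifies for phenotype review with ≥ 2 evidenced carriers
(cardiovascular genes, CVD or FH evidence) or ≥ 1 evidenced carrier
(cancer genes). We read "carriers with supporting phenotypic
information" strictly — the carriers themselves must be evidenced — and
expose the counts as parameters.

Association uses the two-sided Fisher exact test on the 2×2
carrier × evidence table over phenotyped participants (denominator
configurable). The odds ratio and its 95% CI are the conditional
maximum-likelihood estimates — the convention of standard statistical
environments' exact test, which also yields the characteristic single
finite CI bound on zero-cell tables (flagged in the output); the sample
cross-product estimator with a Woolf interval is available as an option.
A table with a zero margin is returned as untestable rather than as a
silent p = 1. No multiple-testing correction alters the star tiers; a
Benjamini–Hochberg FDR column is emitted alongside for transparency.

## Reportability and summaries

P/LP findings are reportable for dominant conditions; semidominant
(LDLR) and X-linked genes are treated as dominant for this purpose.
Recessive findings require biallelic involvement: a homozygote, or two
distinct P/LP variants in the same gene, which are treated as biallelic
without phasing (phase is unavailable in short-read cohort VCFs) and
flagged `phase_unknown`. pVUS findings are never reportable. The
carrier-only tally counts participants whose only P/LP findings are
heterozygous recessive singletons and who are not reportable through
any other gene.

Prevalence intervals use the Wald form (estimate ± z·SE, clamped to
[0, 1]) because the headline estimates are framed as one-proportion
Z-tests; the Wilson score interval is available behind a switch.
Percentages are reported to one decimal with round-half-up by default;
because published summary tables mix round-half-up and truncation,
`format_percent` exposes both conventions explicitly rather than
hard-coding either.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes.

* **Genotypes**: per-variant independent draws from Hardy–Weinberg
  proportions with a cohort-wide inbreeding coefficient F — hom-alt
  q² + Fq(1−q), het 2q(1−q)(1−F). Default F = 0.0375, i.e. roughly 60%
  of participants born to first-cousin-level unions (0.6 × 0.0625), the
  consanguinity regime of the Gulf-region cohorts this tool targets.
  There is no linkage disequilibrium and no pedigree structure; a scalar
  F is sufficient to exercise the heterozygote-deficit and
  recessive-biallelic logic, which is all the pipeline consumes.
* **Classes with count-dependent definitions** (the rare-missense lists
  need MAF < 0.1% *and* > 1 carrier simultaneously) are planted with
  fixed carrier counts, and their carriers' evidence flags are set
  deterministically, so the truth label is exact rather than
  probabilistic. This also fixes a floor on cohort size: at fewer than
  ~2000 participants two carriers already exceed 0.1% MAF, which is why
  the demo configuration (n = 500, 12 variants) plants no LP1/LP2/pVUS
  variants and the full configuration uses n = 2000 with 40 variants
  spanning every class.
* **Near-misses**: for each passing recipe the full configuration also
  plants variants that differ in exactly one field (impact MODERATE,
  PVS1 below Very Strong, MAF above the rarity cut, non-LOF-mechanism
  gene, HGMD conflict, one review star, REVEL below threshold, a single
  carrier, dbSNP-only status, a miscellaneous-category gene, evidence
  absent), all of which must stay unclassified.
* **Phenotypes**: the composite evidence flag per stream is drawn first —
  baseline prevalence p₀ for non-carriers and odds-scaled rate
  OR·p₀/(1−p₀) / (1 + OR·p₀/(1−p₀)) for carriers of an OR-planted
  variant — and then attributed to one concrete component (respecting
  the age gate on early screening). Baseline LDL values are truncated
  below the FH threshold so the composite rate is exact; consequently
  the simulated lipid distribution is not realistic in its upper tail,
  only in its evidence rate. Baselines default to 8% (CVD), 5% (cancer)
  and 6% (FH).
* **Plumbing decoys**: an off-gene site, a non-PASS site, a spanning-
  deletion allele, a multi-allelic line merging two planted variants,
  denormalized indel representations, and decoy transcripts (MANE
  versus more-severe non-MANE, MANE-less pairs decided by rank or
  length).

Fixture bundles (VCF, annotation/phenotype/catalog/region tables,
reference FASTA, truth JSON) are byte-identical for identical configs.

What passing the fixture tests shows: the deterministic rules recover
planted labels exactly, tallies and reportability arithmetic are
correct, and the statistical estimators are calibrated (planted-OR CI
coverage ≈ 95%). What they cannot show: robustness to real-world
annotation noise (discordant transcripts, malformed records beyond the
decoys), population structure beyond a scalar F, or the realism of any
particular evidence rate.

## Problem sizes and numerics

The shipped validation runs use: a 2000-participant, 40-variant cohort
for end-to-end recovery; ~4000 annotation-field combinations (and ~17k
in the unit suite) for classifier/oracle equivalence; exhaustive 2×2
tables to total count 14 plus 300 random tables with margins ≤ 30 for
the Fisher oracle (agreement to 10⁻¹²); 1000 seeded repeat-context
indels for normalization; 100 000 draws per (q, F) cell for the
inbreeding model (3-SD binomial check — at the smallest cell the
expected count is ~2.5, so the z-statistic is discrete and occasionally
exceeds 3 by chance); and 200 replicates of n = 5000 for odds-ratio
coverage. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`.

## Known limitations

Copy-number variants are out of scope, as are alignment and variant
calling upstream of the multisample VCF and any re-derivation of the
upstream annotations (VEP consequences, PVS1 strengths, REVEL scores,
external combinatory verdicts are inputs). The catalog ships with a
curated LOF-mechanism flag that users should review for their purposes.
X-linked genes are treated as dominant for reportability and no sex-
aware dosage model is applied. The Wald interval can extend below zero
for very small numerators before clamping; use the Wilson switch when
that matters.
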