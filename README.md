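# sftriage

Inheritance-aware triage of **ACMG secondary findings** in population
cohorts.

When a large cohort is whole-genome sequenced, a fraction of participants
carry medically actionable variants in the genes of the ACMG secondary-
findings list (v3.1, 78 genes) that are unrelated to any indication for
sequencing but are reportable under ACMG policy. `sftriage` implements a
complete, reusable triage pipeline for this question, aimed at
population-genomics groups screening cohort VCFs — in particular cohorts
from underrepresented and consanguineous populations, where
database-driven classification alone misses population-specific variants
and where recessive-gene carrier rates are clinically relevant.

## What it computes

Starting from a multisample VCF restricted to the catalog genes, variants
are decomposed, left-align-normalized, filtered to passing-filter sites
with cohort minor-allele frequency MAF < 2%, annotated through a single
selected transcript (MANE first, then most severe consequence, then
longest transcript), and assigned to exactly one list:

| List | Rule |
|------|------|
| **P1** | ClinVar P/LP **and** HGMD DM (databases concur) |
| **P2** | ClinVar P/LP, ≥ 2 review gold stars, absent from HGMD |
| **LP1** | Rare (cohort & gnomAD MAF < 0.1%) high-impact LOF variant, PVS1 Very Strong, in a gene with a LOF disease mechanism |
| **LP2** | Rare missense (VUS/conflicting/novel), > 1 carrier, REVEL > 0.7, cancer/CVD gene with cohort disease evidence, external combinatory verdict P/LP |
| **pVUS** | As LP2 but without the external P/LP verdict |
| rejected | ClinVar B/LB, or cohort MAF ≥ 2% |
| unclassified | everything else, incl. ClinVar/HGMD conflicts |

Carriers of classified variants are *genotype-positive participants*
(GPPs). A finding is **reportable** when the list is P/LP and the
condition is dominant (AD/SD/XL), or recessive with biallelic involvement
(homozygous, or two distinct P/LP variants in the gene, phase unknown).
Heterozygous single-variant carriers in recessive genes are flagged
`carrier_only` — not reportable, but relevant for counselling in
consanguineous cohorts. Prevalences come with one-proportion
normal-approximation (Wald) intervals,

p̂ ± z₀.₉₇₅ · √(p̂(1−p̂)/n),

and carrier–phenotype association of LP2/pVUS candidates is tested with
the two-sided Fisher exact test; the odds ratio and 95% CI use the
conditional maximum-likelihood estimator, with significance tiers
\*p < 0.05, \*\*p < 0.01, \*\*\*p < 0.001, \*\*\*\*p < 0.0001.

Because real cohort data of this kind is access-restricted, the package
ships a first-class synthetic-cohort generator
(`sftriage.synthetic_data`) that emulates the study conditions: genotypes
under Hardy–Weinberg with a cohort-wide inbreeding coefficient
(hom-alt = q² + Fq(1−q)), annotation recipes covering every branch of the
decision tree plus adversarial near-misses, and phenotype flags with
planted carrier–phenotype odds ratios.

## Worked example

```bash
sftriage simulate --out bundle --seed 0            # synthetic cohort, n=500
sftriage validate --config bundle/run_config.yaml  # input consistency checks
sftriage run --config bundle/run_config.yaml --out results
```

The run prints (abridged) the JSON report:

```json
{
 "variant_counts": {"P1": 4, "P2": 2, "LP1": 0, "LP2": 0, "pVUS": 0,
                    "rejected": 3, "unclassified": 3},
 "distinct_gpp": 16,
 "reportable_gpp": 13,
 "carrier_only_gpp": 3,
 "prevalence": {"reportable_gpp": {"numerator": 13, "denominator": 500,
                "proportion": 0.026, "ci_low": 0.0121, "ci_high": 0.0399}}
}
```

Reading: of the 12 planted variants, 6 reached the pathogenic lists (4
P1, 2 P2), 3 were rejected (benign or too common) and 3 adversarial
near-misses stayed unclassified. 16 of 500 participants carry a
classified variant; 13 are reportable (2.6% of the cohort, 95% CI
1.2–4.0%), while 3 heterozygous carriers of a recessive Wilson-disease
variant are carrier-only. The per-variant and per-participant tables land
in `results/*.tsv` alongside `report.json`; every count in the report is
reproducible from the tables.

The same objects are available as a library — `run_pipeline`,
`classify_variant`, `prevalence`, `fisher_association`,
`write_fixture_bundle`, … — see the module docstrings.

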