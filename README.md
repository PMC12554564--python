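# genoscreen

Re-implementation of the bespoke computational stages of a clinical
whole-genome-sequencing screening procedure for heritable disorders and
pharmacogenomics (PGx), as a tested, config-driven Python library and CLI.
It is aimed at clinical-bioinformatics engineers who need the decision
logic of such an assay — region extraction, variant filtering, curation
triage, star-allele diplotyping, CNV matching, and validation statistics —
reproducible and exercisable entirely on synthetic and published-table
inputs, without access to patient data.

## What it implements

- **Panel regions** (`genoscreen.panel`): per-gene analysis intervals from
  the selected transcript's exons, extended ±1,000 bp past the first and
  last exon, with comparison exclusion masks (PMS2 exons 9, 11–15 —
  confounded by the *PMS2CL* pseudogene — and MSH3 exon 1); BED output.
- **Variant screening** (`genoscreen.variants`): VCF ingest (pysam),
  multiallelic splitting, allele trimming, the strict VAF < 10% exclusion
  rule, region restriction, and decomposition of multi-nucleotide variants
  (MNVs) into component SNVs with population-frequency lookup.
- **Curation triage** (`genoscreen.triage`): a variant is flagged for
  manual curation iff the auto-classifier tier is P/LP and/or its ClinVar
  interpretation is P, LP, conflicting, or not-provided; unflagged variants
  auto-accept; transition matrices tally initial vs. final five-tier
  (ACMG/AMP) classifications.
- **PGx engine** (`genoscreen.pgx`): table-driven star-allele diplotyping
  for *CYP2C19*, *CYP2C9*, *CYP4F2*, *VKORC1* c.-1639G>A and rs12777823
  from unphased genotypes, with exhaustive haplotype-pair enumeration, a
  documented ambiguity tie-break, and CPIC-style genotype→phenotype
  mapping (metabolizer status, warfarin sensitivity/resistance).
- **CNV matching** (`genoscreen.cnv`): exon-level match decisions (gene,
  type, exact exon span, zygosity / copy-number bound) plus Jaccard and
  reciprocal interval-overlap fractions.
- **Concordance statistics** (`genoscreen.concordance`): gene-level
  positive/negative match logic, 2×2 confirmation tables, sensitivity /
  specificity / PPV / NPV with 95% CIs (Clopper–Pearson exact for
  sensitivity and specificity, logit method for PPV/NPV).
- **Synthetic cohorts** (`genoscreen.simulate`): seed-deterministic VCF
  cohorts with known diplotypes, planted P/LP variants, configurable
  site dropout, and a truth JSON, so every stage round-trips.
- **Pipeline & CLI** (`genoscreen.pipeline`, `genoscreen.cli`): the
  `genoscreen` command orchestrates panel → filter → triage → PGx →
  reports.

## The core model

A star allele of a pharmacogene is a named haplotype defined by a set of
variants; `*1` denotes the default allele negative for every assayed
defining variant. Given unphased dosages g(s) ∈ {0, 1, 2} at the defining
sites of a gene, the caller enumerates all unordered haplotype pairs
(h₁, h₂) with dose(h₁, s) + dose(h₂, s) = g(s) for every s, where each hᵢ
must equal a named allele's defining set exactly or be empty (→ `*1`).
If no pair exists the call is *unresolved* (never a silent `*1/*1`); if
several exist, the pair maximizing the number of non-`*1` alleles is
reported and the call flagged ambiguous with alternatives attached — so a
genotype het at both the *4-core and *17-promoter sites is called
`*4A/*17`, not `*4B/*1`. Diplotypes map to phenotype by allele function:
two reduced-function alleles → poor metabolizer, one → intermediate,
otherwise increased-function alleles give rapid/ultrarapid, else normal.

Diagnostic accuracy against a reference method uses sensitivity
TP/(TP+FN) and specificity TN/(TN+FP), with exact binomial
(Clopper–Pearson) 95% intervals from beta quantiles.

## Worked example

```bash
genoscreen simulate --out demo --samples 2 --seed 4
genoscreen pgx --vcf demo/S000.vcf
```

prints, for the first synthetic sample:

```json
{
 "CYP2C19": {"diplotype": "*2/*17", "phenotype": "Intermediate metabolizer"},
 "CYP2C9":  {"diplotype": "*1/*3",  "phenotype": "Intermediate metabolizer"},
 "CYP4F2":  {"diplotype": "*1/*1",  "phenotype": "Normal warfarin sensitivity"},
 "VKORC1":  {"diplotype": "GG",     "phenotype": "Normal warfarin sensitivity"},
 "rs12777823": {"diplotype": "GG",  "phenotype": "Normal warfarin sensitivity"}
}
```

The sample carries one no-function (*2, *3) allele at each of *CYP2C19*
and *CYP2C9*, hence intermediate metabolizer status for both; it carries
no *CYP4F2* *3 or *VKORC1*/rs12777823 A alleles, so warfarin sensitivity
is normal. `demo/truth.json` records the diplotypes the generator drew,
which the caller recovers exactly.

Validation statistics from a confirmation table (77/78 positives, 874/874
negatives confirmed):

```bash
$ genoscreen concord --tp 77 --fn 1 --tn 874
sensitivity: 98.72% (95% CI 93.06%-99.97%)
specificity: 100.00% (95% CI 99.58%-100.00%)
ppv: 100.00% (95% CI 95.32%-100.00%)
npv: 99.89% (95% CI 99.19%-99.98%)
```

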