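# Methods

## Scope and data model

The package models the decision logic of a clinical WGS screening assay
downstream of alignment and variant calling: it consumes VCFs, tier
annotations, and configuration tables, and produces filtered variant
sets, curation triage decisions, PGx diplotypes/phenotypes, CNV match
verdicts, and diagnostic concordance statistics. Sequencing, alignment,
variant calling, and automated ACMG evidence scoring are upstream systems
whose outputs are inputs here.

Coordinates are 0-based, half-open internally (the BED convention); VCF
positions are converted on ingest and written back 1-based. Contig names
are accepted with or without the `chr` prefix and normalized to the panel
configuration's convention.

## Panel regions

A gene's analysis region is `[first_exon_start − flank, last_exon_end +
flank)`, clamped at zero, with `flank` defaulting to 1,000 bases.
Flanking is symmetric and strand-independent: "upstream and downstream"
is interpreted as both transcript ends regardless of orientation — a
minus-strand gene gets the same genomic interval as a plus-strand gene
with the same exons. No clipping against neighbouring genes is performed.

Exon *numbering*, by contrast, is strand-aware: exon 1 is the 5'-most
exon in transcription direction. Exclusion masks are configured as exon
ranges (PMS2: exon 9 and exons 11–15; MSH3: exon 1) and resolved to
genomic intervals through the gene's exon list, so they stay correct when
coordinates change. Panels ship as editable JSON because transcript exon
coordinates are an annotation choice, not package code; a synthetic demo
panel (`genoscreen.simulate.demo_panel`, regular 150 bp exons) is provided
for testing and carries `-synthetic` transcript labels.

## Variant screening

- **VAF filter**: a call is excluded iff its variant allele fraction is
  *strictly* below the threshold (default 0.10); a call exactly at the
  threshold is retained. VAF is taken from FORMAT/AD as AD_alt / ΣAD,
  falling back to FORMAT/AF; with neither present the call passes with a
  logged warning.
- **Region filter**: a call overlapping a panel region by ≥ 1 base is
  on-panel (boundary-straddling indels therefore count); calls in
  exclusion masks get reason `excluded_region`, others `off_panel`.
  Filter order does not matter (the filters commute) and every removed
  call is written to a filter audit with one reason code.
- **Quality**: an optional `min_qual` (default 20) records `low_qual`
  reasons. The default is a package choice for representing
  borderline-quality calls in audits, not a clinically validated cutoff.
- **Normalization**: alleles are trimmed to minimal representation
  (shared suffix then prefix, leftmost tie-break). Full left-alignment of
  indels requires a reference FASTA and is deliberately not implemented;
  trimmed keys are the comparison currency throughout.
- **MNV decomposition**: a same-length substitution of length ≥ 2 splits
  into one SNV per mismatching position; matching positions emit nothing,
  and applying all components to the reference provably reconstructs the
  alternate (property-tested on 10,000 random cases). Component
  population frequencies come from a TSV lookup (absent → 0), supporting
  re-evaluation of joined MNVs that are absent from population databases
  even though their component SNVs are common. Filtering is applied after
  decomposition.

## Curation triage

`flag = auto_tier ∈ {P, LP} ∨ clinvar ∈ {P, LP, conflicting,
not_provided}`. ClinVar `not_provided` (a record without interpretation)
is distinct from `absent` (no record): only the former triggers curation,
because aggregators conflate the two in ways that change triage volume.
PP5/BP6 evidence is never consulted and has no field in the schema.
Curation itself is a human act: the engine applies a decisions file and
refuses to emit reports or transition matrices while any flagged variant
is `pending`. Unflagged variants auto-accept their initial tier, which
yields the safety property that an auto-classified B/LB variant with
benign-or-silent ClinVar state can never become reportable without
passing through curation. Established risk alleles (e.g. APC
p.Ile1307Lys) are carried on a per-variant flag and reported as
Pathogenic when selected.

## PGx engine

Allele definitions ship as a versioned TSV (`data/allele_definitions.tsv`,
hg19, 1-based positions) sourced from PharmVar/CPIC reference tables;
adding a Tier-2 allele is a table edit, not a code change. Because the
synthetic generator and the caller share the table, the pipeline's logic
is invariant to the specific coordinates; swapping in updated reference
coordinates is a drop-in replacement. The CYP2C9*6 1-bp deletion's
flanking reference base is a placeholder consistent with its VCF
representation.

**Site genotyping.** Every defining site is resolved to an alt dosage.
Sites with no VCF record are hom-ref (a WGS caller emits variant sites
only and the panel sites are within covered regions); an explicit `./.`
record is a no-call; a record carrying a *different* alternate allele is
flagged and contributes dosage 0 to the defining allele. PGx site
genotyping reads the VCF directly (`read_pgx_sites`) rather than through
the screening stream, precisely so that no-calls survive.

**Calling.** Hom-alt sites load both haplotypes; each het site is
assigned to one of the two (2^k assignments for k het sites — k ≤ 3 in
practice for these panels, and bounded by the table). A haplotype is
named iff its variant set equals a named allele's defining set exactly;
the empty set is the default allele. All fully-named unordered pairs are
collected:

- none → `unresolved`, with the evidence attached — never a silent
  default/default call; this is also the outcome when any defining site
  is a no-call (dropout).
- several → ambiguous; the tie-break prefers the pair with the most
  non-default alleles, then canonical allele order. This reproduces the
  observed clinical convention for the *4A/*17 vs *4B/*1 ambiguity and
  always retains the alternatives in the call object.

Suballeles share a core (`*4A`/`*4B` → `*4`) via `core_allele`, enabling
core-level concordance comparison while preserving suballele detail.
VKORC1 and rs12777823 use the same machinery with nucleotide allele names
and ref-first labels (GG/GA/AA).

**Phenotype.** One generalized metabolizer rule drives CYP2C19 and
CYP2C9: 2 reduced-function alleles (no-function or decreased) → Poor; 1 →
Intermediate; else 2 increased → Ultrarapid, 1 increased → Rapid, else
Normal. Under this convention CYP2C9 `*2/*2` is a Poor metabolizer; the
newer CPIC activity-score convention would grade it Intermediate — the
choice is deliberate (it matches the validated assay's reporting) and
lives in the editable function table plus this one rule. CYP4F2: any *3
allele → Warfarin resistant. VKORC1/rs12777823: any A allele → Warfarin
sensitive. Alleles without a function assignment, and unresolved
diplotypes, map to Indeterminate.

## CNV matching

A match requires identical gene, type, and exact exon span, plus
identical zygosity for deletions or satisfaction of the expected
copy-number lower bound for amplifications ("three or more copies" is met
by CN ≥ 3). Near-miss spans return a reason string, never a silent match.
Caller intervals project onto transcript exon numbers with a ≥ 1-base
overlap rule; an interval touching no exon is intronic-only and not a
match candidate. Both Jaccard and reciprocal overlap fractions are
exposed because published overlap percentages rarely state their metric;
Jaccard ≤ reciprocal holds for all pairs (property-tested).

## Concordance statistics

A (sample, gene) comparison is concordant-positive when both methods
report identical non-empty normalized variant sets, concordant-negative
when both are empty, otherwise discordant with the asymmetric difference
retained (test-only → FP, reference-only → FN, both → one of each).
Zygosity joins the match key only when both sides provide it. The
negative-gene denominator of a study depends on per-sample panel
composition and is an explicit input, never inferred.

Sensitivity/specificity CIs are Clopper–Pearson exact (beta quantiles,
closed at 0 and 1); PPV/NPV CIs use the logit-Wald method, falling back
to the exact interval at degenerate proportions — the conventions of
standard diagnostic-test calculators. Metrics with zero denominators are
`undefined`, not 0. Intervals are two-sided 95% with configurable alpha;
report text rounds percentages to 2 decimals.

## Synthetic cohorts

The generator emulates the study conditions: 188 samples by default, with
per-gene diplotype frequencies equal to the published validation-cohort
distribution (shipped as `data/cohort_diplotypes.tsv`), het VAFs Gaussian
around 0.5 (σ = 0.07, a typical 30× binomial spread), depth Poisson
around 30×, and optional per-site dropout emitted as explicit `./.`
records. Planted P/LP variants are specified per sample and recorded,
with everything else, in a truth JSON. One integer seed governs all
randomness; sample *i* draws from an RNG stream keyed `(seed, i)`, so
extending a cohort never perturbs earlier samples and outputs are
byte-identical across runs.

What the generator does *not* model: genotyping error, allelic bias,
sequence context, pseudogene homology, phasing, or read-level artefacts.
Passing round-trip tests therefore demonstrates the correctness of the
decision logic (calling, mapping, triage, matching, statistics) under
clean genotypes — not the robustness of an assay to real sequencing
noise, which only wet validation can show.

## Problem sizes and numerical choices

The test suite exercises the diplotype caller exhaustively against a
brute-force allele-pair enumeration oracle over all 3^k genotype vectors
for a 4-site CYP2C19 subset and the full 6-site CYP2C9 table; round-trip
tests use 60-sample cohorts, and the acceptance script uses the study's
188. Clopper–Pearson agreement with direct binomial-CDF inversion is
checked to 1e-9. Percent summaries round to 1 decimal (cohort tables) or
2 decimals (metric report text), matching the published precision.

## Known limitations

- No reference FASTA handling: indel left-alignment beyond trimming is
  out of scope; inputs are assumed normalized or normalizable by trim.
- CYP2D6 and other highly polymorphic/structural pharmacogenes are out of
  scope, as are gene-deletion or hybrid star alleles.
- The triage engine consumes classifier tiers; it implements no ACMG/AMP
  evidence aggregation of its own.
- CNV calling from read depth is out of scope; the matcher consumes
  called events.
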