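"""Star-allele diplotyping and genotype-to-phenotype mapping.

The engine is definition-table driven.  Each pharmacogene allele is a set
of defining variants (chrom, pos, ref, alt); a sample's diplotype is the
unordered pair of haplotypes that together explain the observed genotypes
at every defining site, where each haplotype matches a named allele's
defining-variant set exactly, or carries no defining variant and is the
default *1.  Because input genotypes are unphased, all consistent pairs
are enumerated; when more than one fully-named pair exists the call is
flagged ambiguous and the pair maximizing the number of non-default
alleles is selected (so a genotype het at both the *4-core site and the
*17 promoter site is reported *4A/*17 rather than *4B/*1, with the
alternative attached).

Genes covered by default: CYP2C19 (Tier 1 *2/*3/*17 and Tier 2
*4A/*4B/*5/*6/*7/*9/*10/*35 plus *8), CYP2C9 (*2/*3/*5/*6/*8/*11), CYP4F2
(*3), VKORC1 c.-1639G>A (rs9923231) and the CYP2C-cluster variant
rs12777823.  VKORC1 and rs12777823 are single-site genotype-style loci
reported as GG/GA/AA rather than star alleles.

Phenotype mapping follows the allele-function table:

- metabolizer genes: two non-normal alleles -> Poor; exactly one
  non-normal (no-function or decreased) -> Intermediate; otherwise two
  increased -> Ultrarapid, one increased -> Rapid, else Normal.  (Under
  this convention CYP2C9 *2/*2 is a Poor metabolizer; the newer
  activity-score convention would call it Intermediate — the rule is a
  deliberate, documented choice and the function table is editable.)
- CYP4F2: any *3 allele -> Warfarin resistant, else Normal warfarin
  sensitivity.
- VKORC1 / rs12777823: any A allele (GA or AA) -> Warfarin sensitive,
  else Normal warfarin sensitivity.

A defining site with no read support (an explicit no-call) makes the
diplotype "unresolved" — the default-*1 rule applies only to assayed
sites with a confident reference genotype, never to missing data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

from genoscreen.variants import VariantCall

__all__ = [
    "AlleleDefinition",
    "GeneDefinitions",
    "SiteGenotypes",
    "DiplotypeCall",
    "PhenotypeCall",
    "load_allele_definitions",
    "load_function_table",
    "load_default_definitions",
    "load_default_functions",
    "load_cohort_distribution",
    "genotype_sites",
    "read_pgx_sites",
    "call_diplotype",
    "map_phenotype",
    "phenotype_for_label",
    "summarize_cohort",
    "core_allele",
    "allele_sort_key",
    "PGX_GENES",
]

SiteKey = tuple[str, int, str, str]

#: Gene reporting styles.  "star" genes have a default *1 allele and star
#: nomenclature; "genotype" loci are single-site and reported as the pair
#: of nucleotide alleles (default letter given).
PGX_GENES: dict[str, tuple[str, str]] = {
    "CYP2C19": ("star", "*1"),
    "CYP2C9": ("star", "*1"),
    "CYP4F2": ("star", "*1"),
    "VKORC1": ("genotype", "G"),
    "rs12777823": ("genotype", "G"),
}

UNRESOLVED = "unresolved"
INDETERMINATE = "Indeterminate"


@dataclass(frozen=True)
class AlleleDefinition:
    """A named allele: its tier and defining-variant set (0-based pos)."""

    gene: str
    allele: str
    tier: int
    defining_variants: frozenset[SiteKey]

    def __post_init__(self) -> None:
        if not self.defining_variants:
            raise ValueError(f"{self.gene} {self.allele}: empty defining set")


@dataclass
class GeneDefinitions:
    """All named alleles of one gene plus its reporting style."""

    gene: str
    alleles: list[AlleleDefinition]
    style: str = "star"
    default_allele: str = "*1"

    def __post_init__(self) -> None:
        seen: dict[frozenset[SiteKey], str] = {}
        for a in self.alleles:
            if a.defining_variants in seen:
                raise ValueError(
                    f"{self.gene}: {a.allele} and {seen[a.defining_variants]} "
                    "share an identical defining-variant set"
                )
            seen[a.defining_variants] = a.allele

    @property
    def sites(self) -> list[SiteKey]:
        """All defining sites of the gene, sorted by position."""
        out = {s for a in self.alleles for s in a.defining_variants}
        return sorted(out, key=lambda s: (s[0], s[1], s[2], s[3]))

    def name_of(self, variant_set: frozenset[SiteKey]) -> str | None:
        """Allele name for an exact defining-variant set; default for empty."""
        if not variant_set:
            return self.default_allele
        for a in self.alleles:
            if a.defining_variants == variant_set:
                return a.allele
        return None


@dataclass
class SiteGenotypes:
    """Per-site genotype map for one sample and gene.

    ``dosages`` maps each defining site to its alternate-allele copy count
    (0 = hom-ref, 1 = het, 2 = hom-alt) or ``None`` for a no-call.
    ``flagged`` lists sites where a different alternate allele was observed;
    their defining-allele dosage is 0 but the observation is retained.
    """

    gene: str
    sample_id: str
    dosages: dict[SiteKey, int | None]
    flagged: list[VariantCall] = field(default_factory=list)


@dataclass
class DiplotypeCall:
    gene: str
    allele_1: str | None
    allele_2: str | None
    resolved: bool = True
    ambiguous: bool = False
    alternatives: list[tuple[str, str]] = field(default_factory=list)
    evidence: dict[SiteKey, int | None] = field(default_factory=dict)
    reason: str | None = None
    sample_id: str = ""

    @property
    def label(self) -> str:
        if not self.resolved:
            return UNRESOLVED
        if self.gene in PGX_GENES and PGX_GENES[self.gene][0] == "genotype":
            return f"{self.allele_1}{self.allele_2}"
        return f"{self.allele_1}/{self.allele_2}"


@dataclass
class PhenotypeCall:
    gene: str
    diplotype: str
    phenotype: str
    sample_id: str = ""


def _parse_table(text: str, n_cols: int) -> Iterable[list[str]]:
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < n_cols:
            raise ValueError(f"short row in table: {line!r}")
        yield fields


def load_allele_definitions(path: str | Path) -> dict[str, GeneDefinitions]:
    """Load a definitions TSV (gene, allele, tier, rsid, chrom, pos, ref, alt).

    ``pos`` in the file is 1-based (VCF convention) and converted to
    0-based internally.
    """
    text = Path(path).read_text()
    return _definitions_from_text(text)


def _definitions_from_text(text: str) -> dict[str, GeneDefinitions]:
    rows: dict[tuple[str, str], dict] = {}
    for gene, allele, tier, _rsid, chrom, pos, ref, alt in _parse_table(text, 8):
        key = (gene, allele)
        entry = rows.setdefault(key, {"tier": int(tier), "sites": set()})
        entry["sites"].add((chrom, int(pos) - 1, ref, alt))
    genes: dict[str, GeneDefinitions] = {}
    for (gene, allele), entry in rows.items():
        style, default = PGX_GENES.get(gene, ("star", "*1"))
        gd = genes.setdefault(gene, GeneDefinitions(gene, [], style, default))
        gd.alleles.append(
            AlleleDefinition(gene, allele, entry["tier"], frozenset(entry["sites"]))
        )
    for gd in genes.values():
        GeneDefinitions(gd.gene, gd.alleles, gd.style, gd.default_allele)  # re-validate
    return genes


def load_function_table(path: str | Path) -> dict[tuple[str, str], str]:
    text = Path(path).read_text()
    return {
        (gene, allele): fn for gene, allele, fn in _parse_table(text, 3)
    }


def _data_text(name: str) -> str:
    return resources.files("genoscreen.data").joinpath(name).read_text()


def load_default_definitions() -> dict[str, GeneDefinitions]:
    """Shipped allele-definition table (hg19 coordinates)."""
    return _definitions_from_text(_data_text("allele_definitions.tsv"))


def load_default_functions() -> dict[tuple[str, str], str]:
    return {
        (gene, allele): fn
        for gene, allele, fn in _parse_table(_data_text("allele_functions.tsv"), 3)
    }


def load_cohort_distribution(
    path: str | Path | None = None,
) -> list[tuple[str, str, int]]:
    """Validation-cohort diplotype distribution (gene, diplotype, count)."""
    text = Path(path).read_text() if path else _data_text("cohort_diplotypes.tsv")
    return [
        (gene, dip, int(n)) for gene, dip, n in _parse_table(text, 3)
    ]


# ---------------------------------------------------------------------------
# site genotyping


def genotype_sites(
    calls: Iterable[VariantCall],
    defs: GeneDefinitions,
    sample_id: str = "",
) -> SiteGenotypes:
    """Resolve each defining site of a gene to an alt dosage.

    Sites with no record are hom-ref (dosage 0): a WGS caller emits only
    variant sites, and defining sites are within covered regions.  An
    explicit no-call record makes the site ``None``.  A record whose alt
    differs from the defining alt is flagged; the defining dosage stays 0.
    """
    sites = defs.sites
    by_pos: dict[tuple[str, int], list[SiteKey]] = {}
    for s in sites:
        by_pos.setdefault((s[0], s[1]), []).append(s)
    dosages: dict[SiteKey, int | None] = {s: 0 for s in sites}
    flagged: list[VariantCall] = []
    for v in calls:
        matches = by_pos.get((v.chrom, v.pos))
        if not matches:
            continue
        hit = next(
            (s for s in matches if s[2] == v.ref and s[3] == v.alt), None
        )
        if v.genotype == "no-call":
            for s in matches:
                dosages[s] = None
            continue
        if hit is None:
            flagged.append(v)
            continue
        dosages[hit] = {"het": 1, "hemi": 1, "hom": 2}[v.genotype]
    return SiteGenotypes(defs.gene, sample_id, dosages, flagged)


def read_pgx_sites(
    vcf_path: str | Path,
    defs: GeneDefinitions,
    sample: str | None = None,
) -> SiteGenotypes:
    """Genotype a gene's defining sites directly from a VCF.

    Unlike the screening variant stream, this path retains explicit
    no-call records (GT = ./.) so missing coverage at a defining site
    propagates to an unresolved diplotype.
    """
    sites = defs.sites
    wanted_pos = {(s[0].removeprefix("chr"), s[1]) for s in sites}
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        names = list(vcf.header.samples)
        sname = sample if sample is not None else names[0]
        for rec in vcf:
            if (rec.chrom.removeprefix("chr"), rec.start) not in wanted_pos:
                continue
            gt = rec.samples[sname].get("GT")
            chrom = rec.chrom if rec.chrom.startswith("chr") else f"chr{rec.chrom}"
            if gt is None or all(a is None for a in gt):
                # explicit no-call: use a placeholder alt so VariantCall validates
                alts = rec.alts or ("N",)
                calls.append(
                    VariantCall(
                        chrom, rec.start, rec.ref, alts[0] if alts[0] else "N",
                        genotype="no-call", sample_id=sname,
                    )
                )
                continue
            if rec.alts is None:
                continue
            for ai, alt in enumerate(rec.alts, start=1):
                if alt is None:
                    continue
                n_alt = sum(1 for a in gt if a == ai)
                n_called = sum(1 for a in gt if a is not None)
                if n_alt == 0:
                    continue
                genotype = (
                    "hom" if n_alt == n_called and n_called > 1
                    else "hemi" if n_called == 1
                    else "het"
                )
                calls.append(
                    VariantCall(
                        chrom, rec.start, rec.ref, alt,
                        genotype=genotype, sample_id=sname,
                    )
                )
    return genotype_sites(calls, defs, sample_id=sname)


# ---------------------------------------------------------------------------
# diplotype calling


_ALLELE_RE = re.compile(r"^\*(\d+)([A-Z]*)$")


def allele_sort_key(name: str) -> tuple:
    """Canonical allele ordering: *1 < *2 < *4A < *4B < *17; letters after
    numbers for star alleles, plain lexicographic otherwise."""
    m = _ALLELE_RE.match(name)
    if m:
        return (0, int(m.group(1)), m.group(2))
    return (1, name)


def core_allele(name: str) -> str:
    """Core allele of a suballele: *4A and *4B -> *4 (same core phenotype)."""
    m = _ALLELE_RE.match(name)
    if m:
        return f"*{m.group(1)}"
    return name


def _canonical_pair(a: str, b: str, defs: GeneDefinitions | None = None) -> tuple[str, str]:
    if defs is not None and defs.style == "genotype":
        # reference-first convention: GG / GA / AA
        return tuple(sorted((a, b), key=lambda x: x != defs.default_allele))  # type: ignore[return-value]
    return tuple(sorted((a, b), key=allele_sort_key))  # type: ignore[return-value]


def call_diplotype(
    genotypes: SiteGenotypes, defs: GeneDefinitions
) -> DiplotypeCall:
    """Enumerate haplotype pairs consistent with unphased site dosages.

    Hom-alt sites load both haplotypes; each het site is assigned to one of
    the two.  A pair is valid when both haplotypes are exactly a named
    allele or empty (the default allele).  With no valid pair the call is
    ``unresolved`` (never a silent default/default); with several, the
    documented tie-break picks the pair with the most non-default alleles
    and records the rest as alternatives.
    """
    dosages = genotypes.dosages
    missing = [s for s in defs.sites if s not in dosages]
    if missing:
        raise ValueError(f"{defs.gene}: genotypes missing defining sites {missing}")
    no_calls = [s for s, d in dosages.items() if d is None]
    if no_calls:
        return DiplotypeCall(
            defs.gene, None, None, resolved=False,
            reason=f"no-call at {len(no_calls)} defining site(s)",
            evidence=dict(dosages), sample_id=genotypes.sample_id,
        )
    hom = [s for s, d in dosages.items() if d == 2]
    het = [s for s, d in dosages.items() if d == 1]
    pairs: dict[tuple[str, str], None] = {}
    for assignment in product((0, 1), repeat=len(het)):
        h = (set(hom), set(hom))
        for site, side in zip(het, assignment):
            h[side].add(site)
        n1 = defs.name_of(frozenset(h[0]))
        n2 = defs.name_of(frozenset(h[1]))
        if n1 is None or n2 is None:
            continue
        pairs.setdefault(_canonical_pair(n1, n2, defs))
    if not pairs:
        return DiplotypeCall(
            defs.gene, None, None, resolved=False,
            reason="no consistent pair of named haplotypes",
            evidence=dict(dosages), sample_id=genotypes.sample_id,
        )
    ranked = sorted(
        pairs,
        key=lambda p: (
            -sum(1 for a in p if a != defs.default_allele),
            allele_sort_key(p[0]),
            allele_sort_key(p[1]),
        ),
    )
    best = ranked[0]
    return DiplotypeCall(
        defs.gene, best[0], best[1],
        ambiguous=len(ranked) > 1,
        alternatives=ranked[1:],
        evidence=dict(dosages),
        sample_id=genotypes.sample_id,
    )


# ---------------------------------------------------------------------------
# phenotype mapping


def _metabolizer_label(f1: str, f2: str) -> str:
    fns = (f1, f2)
    reduced = sum(f in ("no_function", "decreased") for f in fns)
    increased = sum(f == "increased" for f in fns)
    if reduced == 2:
        return "Poor metabolizer"
    if reduced == 1:
        return "Intermediate metabolizer"
    if increased == 2:
        return "Ultrarapid metabolizer"
    if increased == 1:
        return "Rapid metabolizer"
    return "Normal metabolizer"


def map_phenotype(
    d: DiplotypeCall,
    function_table: Mapping[tuple[str, str], str] | None = None,
) -> PhenotypeCall:
    """Map a diplotype to its phenotype label via the function table."""
    if function_table is None:
        function_table = load_default_functions()
    if not d.resolved:
        return PhenotypeCall(d.gene, UNRESOLVED, INDETERMINATE, d.sample_id)
    label = _phenotype_label(
        d.gene, d.allele_1, d.allele_2, function_table
    )
    return PhenotypeCall(d.gene, d.label, label, d.sample_id)


def _phenotype_label(
    gene: str,
    a1: str,
    a2: str,
    function_table: Mapping[tuple[str, str], str],
) -> str:
    if gene == "CYP4F2":
        return (
            "Warfarin resistant"
            if "*3" in (core_allele(a1), core_allele(a2))
            else "Normal warfarin sensitivity"
        )
    style = PGX_GENES.get(gene, ("star", "*1"))[0]
    if style == "genotype":
        return (
            "Warfarin sensitive"
            if "A" in (a1, a2)
            else "Normal warfarin sensitivity"
        )
    f1 = function_table.get((gene, a1))
    f2 = function_table.get((gene, a2))
    if f1 is None or f2 is None:
        return INDETERMINATE
    return _metabolizer_label(f1, f2)


def phenotype_for_label(
    gene: str,
    diplotype: str,
    function_table: Mapping[tuple[str, str], str] | None = None,
) -> str:
    """Phenotype for a printed diplotype label ("*2/*17", "GA", ...)."""
    if function_table is None:
        function_table = load_default_functions()
    if diplotype == UNRESOLVED:
        return INDETERMINATE
    if "/" in diplotype:
        a1, a2 = diplotype.split("/")
    elif len(diplotype) == 2:
        a1, a2 = diplotype[0], diplotype[1]
    else:
        raise ValueError(f"cannot parse diplotype label {diplotype!r}")
    return _phenotype_label(gene, a1, a2, function_table)


# ---------------------------------------------------------------------------
# cohort summaries


def summarize_cohort(
    calls: Sequence[DiplotypeCall] | Sequence[PhenotypeCall],
) -> "pd.DataFrame":
    """Per-gene counts and percentages (1 decimal) of diplotypes or
    phenotypes.  Percent denominators are samples with a call for the gene.
    Duplicate (sample, gene) pairs are an error.
    """
    import pandas as pd

    seen: set[tuple[str, str]] = set()
    rows = []
    for c in calls:
        key = (c.sample_id, c.gene)
        if c.sample_id and key in seen:
            raise ValueError(f"duplicate sample-gene pair {key}")
        seen.add(key)
        label = c.label if isinstance(c, DiplotypeCall) else c.phenotype
        rows.append({"gene": c.gene, "category": label})
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["gene", "category", "n", "percent"])
    out = (
        df.groupby(["gene", "category"]).size().reset_index(name="n")
    )
    totals = out.groupby("gene")["n"].transform("sum")
    out["percent"] = (100.0 * out["n"] / totals).round(1)
    return out.sort_values(
        ["gene", "n"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)
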