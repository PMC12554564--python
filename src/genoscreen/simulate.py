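"""Synthetic VCF cohorts with known truth.

Generates per-sample VCFs whose pharmacogene defining-site genotypes are
consistent with diplotypes drawn from a configurable per-gene frequency
table (default: the 188-sample validation-cohort distribution shipped with
the package), plus optional planted panel P/LP variants, and writes a
truth JSON recording every planted fact.  This makes every downstream
stage — site genotyping, diplotype calling, phenotype mapping, triage,
concordance — testable end to end without any external data.

Determinism: a single integer seed governs all randomness.  Each sample
draws from its own RNG stream keyed by ``(seed, sample_index)``, so adding
samples to a cohort never perturbs the output of earlier samples.

Realism boundaries: emitted genotypes are exact (no genotyping error
model), het VAFs are Gaussian around 0.5, depth is Poisson around 30x, and
there is no read-level or sequence-context simulation.  ``dropout_rate``
emits a defining site as an explicit no-call (./.) with the given
per-site probability, emulating missing coverage.

The module also ships a small synthetic demo panel (synthetic exon
coordinates, real gene symbols) and a joined-MNV fixture for the
decomposition path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from genoscreen.panel import PanelConfig, PanelGene
from genoscreen.pgx import (
    GeneDefinitions,
    SiteKey,
    load_cohort_distribution,
    load_default_definitions,
)
from genoscreen.variants import VariantCall

__all__ = [
    "PlantedVariant",
    "CohortSpec",
    "SampleTruth",
    "CohortTruth",
    "generate_cohort",
    "generate_mnv_case",
    "demo_panel",
    "default_diplotype_frequencies",
]


@dataclass(frozen=True)
class PlantedVariant:
    """A panel small variant planted into one sample of the cohort."""

    sample_index: int
    gene: str
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    tier: str = "P"
    genotype: str = "het"


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    ``diplotype_frequencies`` maps gene -> {diplotype label: probability};
    the default is the shipped validation-cohort distribution.  ``vaf_sd``
    is the Gaussian spread of heterozygous VAFs around 0.5.
    """

    n_samples: int = 188
    seed: int = 0
    diplotype_frequencies: dict[str, dict[str, float]] | None = None
    planted_plp: list[PlantedVariant] = field(default_factory=list)
    vaf_sd: float = 0.07
    dropout_rate: float = 0.0
    mean_depth: int = 30

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must lie in [0,1]")
        if self.diplotype_frequencies is None:
            self.diplotype_frequencies = default_diplotype_frequencies()
        for gene, freqs in self.diplotype_frequencies.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"{gene}: diplotype frequencies sum to {total}, not 1"
                )


@dataclass
class SampleTruth:
    sample_id: str
    diplotypes: dict[str, str]
    planted: list[PlantedVariant] = field(default_factory=list)
    no_call_sites: int = 0


@dataclass
class CohortTruth:
    spec_seed: int
    samples: list[SampleTruth]
    vcf_paths: list[Path] = field(default_factory=list)


def default_diplotype_frequencies() -> dict[str, dict[str, float]]:
    """Per-gene diplotype probabilities from the shipped cohort counts."""
    dist = load_cohort_distribution()
    out: dict[str, dict[str, float]] = {}
    totals: dict[str, int] = {}
    for gene, dip, n in dist:
        out.setdefault(gene, {})[dip] = n
        totals[gene] = totals.get(gene, 0) + n
    return {
        gene: {dip: n / totals[gene] for dip, n in dips.items()}
        for gene, dips in out.items()
    }


def _alleles_of(label: str, gene: str) -> tuple[str, str]:
    if "/" in label:
        a, b = label.split("/")
        return a, b
    if len(label) == 2:
        return label[0], label[1]
    raise ValueError(f"cannot parse diplotype label {label!r} for {gene}")


def _dosages_for_diplotype(
    label: str, defs: GeneDefinitions
) -> dict[SiteKey, int]:
    """Alt-allele dosage at each defining site implied by a diplotype."""
    dosages: dict[SiteKey, int] = {s: 0 for s in defs.sites}
    by_name = {a.allele: a.defining_variants for a in defs.alleles}
    for allele in _alleles_of(label, defs.gene):
        if allele == defs.default_allele:
            continue
        if allele not in by_name:
            raise ValueError(f"{defs.gene}: no definition for allele {allele!r}")
        for site in by_name[allele]:
            dosages[site] += 1
    return dosages


_VCF_HEADER = """\
##fileformat=VCFv4.2
##FILTER=<ID=PASS,Description="All filters passed">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def _contig_lines(chroms: Sequence[str]) -> str:
    return "".join(f"##contig=<ID={c}>\n" for c in chroms)


def _format_record(
    chrom: str,
    pos0: int,
    ref: str,
    alt: str,
    gt: str,
    depth: int,
    vaf: float | None,
    qual: float = 50.0,
) -> str:
    if gt == "./.":
        sample = f"./.:.:{depth}"
        return (
            f"{chrom}\t{pos0 + 1}\t.\t{ref}\t{alt}\t.\t.\t.\tGT:AD:DP\t{sample}"
        )
    n_alt = round(depth * (vaf if vaf is not None else 0.5))
    n_alt = min(max(n_alt, 1), depth)
    ad = f"{depth - n_alt},{n_alt}"
    return (
        f"{chrom}\t{pos0 + 1}\t.\t{ref}\t{alt}\t{qual:.2f}\tPASS\t.\t"
        f"GT:AD:DP\t{gt}:{ad}:{depth}"
    )


def _chrom_key(chrom: str) -> tuple[int, str]:
    bare = chrom.removeprefix("chr")
    return (int(bare), "") if bare.isdigit() else (99, bare)


def generate_cohort(
    spec: CohortSpec,
    out_dir: str | Path,
    definitions: Mapping[str, GeneDefinitions] | None = None,
) -> CohortTruth:
    """Write one VCF per sample plus ``truth.json``; return the truth.

    Sample ``i`` is named ``S%03d`` and written to ``S%03d.vcf``.  Output
    is byte-identical for identical specs.
    """
    if definitions is None:
        definitions = load_default_definitions()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genes = sorted(spec.diplotype_frequencies)
    planted_by_sample: dict[int, list[PlantedVariant]] = {}
    for pv in spec.planted_plp:
        if not 0 <= pv.sample_index < spec.n_samples:
            raise ValueError(f"planted variant sample_index {pv.sample_index} out of range")
        planted_by_sample.setdefault(pv.sample_index, []).append(pv)

    truth = CohortTruth(spec_seed=spec.seed, samples=[])
    for i in range(spec.n_samples):
        rng = np.random.default_rng([abs(spec.seed) % (2**31), i])
        sample_id = f"S{i:03d}"
        diplotypes: dict[str, str] = {}
        records: list[tuple[str, int, str]] = []  # (chrom, pos, line)
        n_no_call = 0
        for gene in genes:
            defs = definitions.get(gene)
            if defs is None:
                raise ValueError(f"no allele definitions for gene {gene!r}")
            freqs = spec.diplotype_frequencies[gene]
            labels = sorted(freqs)
            probs = np.array([freqs[l] for l in labels])
            label = labels[int(rng.choice(len(labels), p=probs / probs.sum()))]
            diplotypes[gene] = label
            dosages = _dosages_for_diplotype(label, defs)
            for site in defs.sites:
                chrom, pos, ref, alt = site
                dropped = (
                    spec.dropout_rate > 0.0
                    and rng.random() < spec.dropout_rate
                )
                depth = max(1, int(rng.poisson(spec.mean_depth)))
                if dropped:
                    n_no_call += 1
                    records.append(
                        (chrom, pos, _format_record(chrom, pos, ref, alt, "./.", 0, None))
                    )
                    continue
                d = dosages[site]
                if d == 0:
                    continue
                gt = "0/1" if d == 1 else "1/1"
                vaf = (
                    float(np.clip(rng.normal(0.5, spec.vaf_sd), 0.15, 0.85))
                    if d == 1
                    else float(np.clip(rng.normal(0.98, 0.02), 0.9, 1.0))
                )
                records.append(
                    (chrom, pos, _format_record(chrom, pos, ref, alt, gt, depth, vaf))
                )
        for pv in planted_by_sample.get(i, []):
            depth = max(1, int(rng.poisson(spec.mean_depth)))
            gt = "0/1" if pv.genotype == "het" else "1/1"
            vaf = (
                float(np.clip(rng.normal(0.5, spec.vaf_sd), 0.15, 0.85))
                if pv.genotype == "het"
                else 1.0
            )
            records.append(
                (pv.chrom, pv.pos, _format_record(pv.chrom, pv.pos, pv.ref, pv.alt, gt, depth, vaf))
            )
        records.sort(key=lambda r: (_chrom_key(r[0]), r[1]))
        chroms = sorted({r[0] for r in records}, key=_chrom_key)
        path = out_dir / f"{sample_id}.vcf"
        with open(path, "w") as fh:
            fh.write(_VCF_HEADER)
            fh.write(_contig_lines(chroms))
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                f"{sample_id}\n"
            )
            for _, _, line in records:
                fh.write(line + "\n")
        truth.vcf_paths.append(path)
        truth.samples.append(
            SampleTruth(
                sample_id=sample_id,
                diplotypes=diplotypes,
                planted=planted_by_sample.get(i, []),
                no_call_sites=n_no_call,
            )
        )
    _write_truth_json(truth, out_dir / "truth.json")
    return truth


def _write_truth_json(truth: CohortTruth, path: Path) -> None:
    payload = {
        "seed": truth.spec_seed,
        "samples": [
            {
                "sample_id": s.sample_id,
                "diplotypes": s.diplotypes,
                "planted": [
                    {
                        "gene": p.gene,
                        "chrom": p.chrom,
                        "pos": p.pos,
                        "ref": p.ref,
                        "alt": p.alt,
                        "tier": p.tier,
                        "genotype": p.genotype,
                    }
                    for p in s.planted
                ],
                "no_call_sites": s.no_call_sites,
            }
            for s in truth.samples
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# MNV fixture


def generate_mnv_case() -> tuple[VariantCall, dict[tuple[str, int, str, str], float]]:
    """A joined dinucleotide substitution whose component SNVs are common.

    Mimics the failure mode where a caller joins two adjacent common SNVs
    into one MNV that is absent from population databases: the parent has
    AF 0 in the table while each component SNV is present at high
    frequency, so decomposition supports a benign interpretation.
    """
    parent = VariantCall(
        chrom="chr17",
        pos=7_579_470,
        ref="GG",
        alt="AC",
        genotype="het",
        depth=32,
        vaf=0.48,
        qual=60.0,
        sample_id="MNV1",
    )
    af_table = {
        ("chr17", 7_579_470, "G", "A"): 0.21,
        ("chr17", 7_579_471, "G", "C"): 0.18,
    }
    return parent, af_table


# ---------------------------------------------------------------------------
# demo panel (synthetic coordinates)


def demo_panel(flank: int = 1000) -> PanelConfig:
    """A miniature heritable-disorder panel with synthetic exon coordinates.

    Gene symbols are real panel members; exon coordinates are synthetic
    (regular 150-base exons spaced 1.5 kb apart) so no reference download
    is needed.  PMS2 is placed on the minus strand so the pseudogene
    exclusion mask (exon 9 and exons 11-15, transcript numbering) and
    MSH3's exon-1 mask exercise strand-aware exon numbering.
    """

    def exons(start: int, n: int) -> list[tuple[int, int]]:
        return [(start + i * 1500, start + i * 1500 + 150) for i in range(n)]

    genes = [
        PanelGene("BRCA1", "chr17", "NM_007294-synthetic", exons(41_200_000, 23), "-"),
        PanelGene("TP53", "chr17", "NM_000546-synthetic", exons(7_570_000, 11), "-"),
        PanelGene("MUTYH", "chr1", "NM_001128425-synthetic", exons(45_790_000, 16), "-"),
        PanelGene("APC", "chr5", "NM_000038-synthetic", exons(112_040_000, 16), "+"),
        PanelGene("MSH2", "chr2", "NM_000251-synthetic", exons(47_630_000, 16), "+"),
        PanelGene("MLH1", "chr3", "NM_000249-synthetic", exons(37_030_000, 19), "+"),
        PanelGene("MSH3", "chr5", "NM_002439-synthetic", exons(79_950_000, 24), "+"),
        PanelGene("PMS2", "chr7", "NM_000535-synthetic", exons(6_010_000, 15), "-"),
    ]
    return PanelConfig(genes=genes, flank_bases=flank)
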