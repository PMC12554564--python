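"""Small-variant ingest, normalization, and screening filters.

Variants arrive as VCF v4.x with GT and AD (or AF) FORMAT fields.  On
ingest, multiallelic records are split into biallelic observations, alleles
are trimmed to their minimal representation, positions are converted to
0-based, and each call is tagged with the panel gene whose analysis region
contains it.

Two screening filters mirror the clinical procedure:

- the allele-fraction filter removes calls with VAF strictly below the
  threshold (default 10%; a call exactly at the threshold is retained);
- the region filter removes calls outside every panel region
  (``off_panel``) or inside a comparison exclusion mask
  (``excluded_region``).

An optional quality filter (``--min-qual``, default 20 — a documented
package choice, not a clinically validated cutoff) records low-quality
calls so that borderline caller output (e.g. a Qual ~5 variant on two
supporting reads) is representable in audits.

MNV decomposition splits a same-length substitution into its component
SNVs — one per mismatching position — and attaches population allele
frequencies from a lookup table, so that a joined MNV absent from
population databases can be re-evaluated as separate common SNVs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pysam

from genoscreen.panel import Interval, PanelConfig, PanelRegion, normalize_chrom

__all__ = [
    "VariantCall",
    "DecompositionResult",
    "VcfParseError",
    "read_vcf",
    "filter_vaf",
    "filter_qual",
    "restrict_to_regions",
    "decompose_mnv",
    "load_af_table",
    "write_filter_audit",
]

log = logging.getLogger(__name__)

DEFAULT_MIN_QUAL = 20.0


class VcfParseError(ValueError):
    """Malformed VCF input; message carries the offending record."""


@dataclass
class VariantCall:
    """One normalized biallelic small-variant observation.

    ``pos`` is the 0-based start of the trimmed alleles.  ``genotype`` is
    one of ``het`` / ``hom`` / ``hemi`` / ``no-call``.  ``filtered`` with a
    ``filter_reason`` code marks a call removed from analysis; the call is
    retained in audits.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str = "het"
    depth: int = 0
    vaf: float | None = None
    qual: float | None = None
    sample_id: str = ""
    gene: str | None = None
    filtered: bool = False
    filter_reason: str | None = None

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.vaf is not None and not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf {self.vaf} outside [0,1]")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def end(self) -> int:
        """0-based half-open end on the reference."""
        return self.pos + len(self.ref)

    def interval(self) -> Interval:
        return Interval(self.chrom, self.pos, self.end)


@dataclass
class DecompositionResult:
    """An MNV with its component SNVs and their population frequencies."""

    parent: VariantCall
    components: list[VariantCall]
    component_afs: list[float]
    decomposed: bool = True


def trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal representation: strip shared suffix, then shared prefix.

    Ties in representation are broken toward the leftmost (prefix stripping
    advances ``pos``).  At least one base of each allele is always kept.
    Full left-alignment of indels against the reference sequence requires a
    FASTA and is out of scope; trimmed representation is the comparison key.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _genotype_label(gt: tuple, allele_index: int) -> str:
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return "no-call"
    carrying = [a for a in alleles if a == allele_index]
    if not carrying:
        return "no-call"
    if len(alleles) == 1:
        return "hemi"
    if all(a == allele_index for a in alleles):
        return "hom"
    return "het"


def read_vcf(
    path: str | Path,
    panel: PanelConfig | None = None,
    sample: str | None = None,
) -> Iterator[VariantCall]:
    """Stream normalized biallelic calls from a VCF.

    Multiallelic records are split with per-allele VAF recomputed from AD.
    Records without GT are skipped with a warning.  Only alleles carried by
    the genotype are emitted (a split allele the sample does not carry is
    not an observation).  When ``panel`` is given, each call is tagged with
    the containing gene's symbol, with contig names normalized to the
    panel's convention.
    """
    use_prefix = True
    region_index: list[PanelRegion] = []
    if panel is not None:
        region_index = panel.regions()
        use_prefix = any(g.chrom.startswith("chr") for g in panel.genes)
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    with vcf:
        sample_names = list(vcf.header.samples)
        if sample is not None and sample not in sample_names:
            raise VcfParseError(f"sample {sample!r} not in VCF {path}")
        use_samples = [sample] if sample is not None else sample_names
        for rec in vcf:
            if rec.alts is None:
                continue
            for sname in use_samples:
                fmt = rec.samples[sname]
                gt = fmt.get("GT")
                if gt is None or all(a is None for a in gt):
                    log.warning(
                        "skipping record %s:%s in %s: missing GT",
                        rec.chrom,
                        rec.pos,
                        sname,
                    )
                    continue
                ad = fmt.get("AD")
                af = fmt.get("AF")
                depth = fmt.get("DP")
                if depth is None and ad is not None:
                    depth = int(sum(a for a in ad if a is not None))
                for ai, alt in enumerate(rec.alts, start=1):
                    if alt is None or alt in (".", "*"):
                        continue
                    genotype = _genotype_label(tuple(gt), ai)
                    if genotype == "no-call":
                        continue
                    vaf: float | None = None
                    if ad is not None and len(ad) > ai and ad[ai] is not None:
                        total = sum(a for a in ad if a is not None)
                        vaf = ad[ai] / total if total > 0 else None
                    elif af is not None:
                        af_seq = af if isinstance(af, tuple) else (af,)
                        if len(af_seq) >= ai and af_seq[ai - 1] is not None:
                            vaf = float(af_seq[ai - 1])
                    if vaf is None:
                        log.warning(
                            "no AD/AF at %s:%s — VAF filter will pass this call",
                            rec.chrom,
                            rec.pos,
                        )
                    pos, ref_a, alt_a = trim_alleles(rec.start, rec.ref, alt)
                    chrom = rec.chrom
                    if panel is not None:
                        chrom = normalize_chrom(chrom, use_prefix)
                    call = VariantCall(
                        chrom=chrom,
                        pos=pos,
                        ref=ref_a,
                        alt=alt_a,
                        genotype=genotype,
                        depth=int(depth) if depth is not None else 0,
                        vaf=vaf,
                        qual=rec.qual,
                        sample_id=sname,
                    )
                    if region_index:
                        call.gene = _containing_gene(call, region_index)
                    yield call


def _containing_gene(v: VariantCall, regions: Sequence[PanelRegion]) -> str | None:
    iv = v.interval()
    for r in regions:
        if r.interval.overlaps(iv):
            return r.symbol
    return None


def filter_vaf(v: VariantCall, threshold: float = 0.10) -> VariantCall:
    """Mark a call filtered (reason ``low_vaf``) iff its VAF is strictly
    below the threshold; a VAF exactly at the threshold is retained.
    Calls with no VAF pass (annotated fields are assumed present upstream).
    """
    if v.vaf is not None and v.vaf < threshold:
        return replace(v, filtered=True, filter_reason="low_vaf")
    return v


def filter_qual(v: VariantCall, min_qual: float = DEFAULT_MIN_QUAL) -> VariantCall:
    """Mark a call filtered (reason ``low_qual``) iff qual < min_qual."""
    if v.qual is not None and v.qual < min_qual:
        return replace(v, filtered=True, filter_reason="low_qual")
    return v


def restrict_to_regions(
    v: VariantCall, regions: Sequence[PanelRegion]
) -> VariantCall:
    """Apply the panel-region restriction.

    A call overlapping no region by at least one base is ``off_panel``.  A
    call overlapping an exclusion mask is ``excluded_region``.  A
    boundary-straddling variant counts as on-panel if it overlaps a region
    by >= 1 base.
    """
    iv = v.interval()
    containing = [r for r in regions if r.interval.overlaps(iv)]
    if not containing:
        return replace(v, filtered=True, filter_reason="off_panel", gene=None)
    for r in containing:
        for mask in r.exclusions:
            if mask.overlaps(iv):
                return replace(
                    v, filtered=True, filter_reason="excluded_region",
                    gene=r.symbol,
                )
    return replace(v, gene=containing[0].symbol)


def decompose_mnv(
    v: VariantCall,
    af_table: Mapping[tuple[str, int, str, str], float] | None = None,
) -> DecompositionResult:
    """Split a same-length substitution MNV into component SNVs.

    One component per position where ref and alt disagree; matching
    positions emit nothing.  Component population allele frequencies are
    looked up in ``af_table`` (absent → 0.0).  Length-changing variants are
    not decomposable and come back unchanged with ``decomposed=False``.
    """
    if len(v.ref) != len(v.alt) or len(v.ref) < 2:
        return DecompositionResult(v, [v], [_af_lookup(af_table, v.key)], False)
    components: list[VariantCall] = []
    afs: list[float] = []
    for offset, (r, a) in enumerate(zip(v.ref, v.alt)):
        if r == a:
            continue
        snv = replace(v, pos=v.pos + offset, ref=r, alt=a)
        components.append(snv)
        afs.append(_af_lookup(af_table, snv.key))
    return DecompositionResult(v, components, afs, True)


def _af_lookup(
    table: Mapping[tuple[str, int, str, str], float] | None,
    key: tuple[str, int, str, str],
) -> float:
    if table is None:
        return 0.0
    return float(table.get(key, 0.0))


def load_af_table(path: str | Path) -> dict[tuple[str, int, str, str], float]:
    """Population AF table: TSV with columns chrom, pos (0-based), ref, alt, af."""
    table: dict[tuple[str, int, str, str], float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            chrom, pos, ref, alt, af = line.split("\t")[:5]
            table[(chrom, int(pos), ref, alt)] = float(af)
    return table


def write_filter_audit(calls: Sequence[VariantCall], path: str | Path) -> None:
    """One row per filtered call with its reason code."""
    with open(path, "w") as fh:
        fh.write("sample_id\tchrom\tpos\tref\talt\tgene\treason\n")
        for v in calls:
            if not v.filtered:
                continue
            fh.write(
                f"{v.sample_id}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}"
                f"\t{v.gene or '.'}\t{v.filter_reason}\n"
            )
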