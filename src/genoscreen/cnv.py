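"""Exon-level CNV/SV event matching.

Observed copy-number events are compared against expected events at exon
resolution: a match requires the same gene, the same event type, exactly
the same exon span (transcript exon numbers, 1-based inclusive) and — for
deletions — the same zygosity.  Amplifications match when the observed
copy number satisfies the expected bound (an expected "three or more
copies" is met by any observed copy number >= 3).  Near-miss spans are
reported with a reason, never auto-matched.

Caller output arrives as genomic intervals; :func:`project_to_exons`
projects an interval onto a panel gene's transcript exon numbering with a
>= 1-base overlap rule, so interval-space calls can be compared to
exon-space truth.  :func:`interval_overlap` provides the Jaccard and
reciprocal-overlap fractions used for large-deletion interval comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

from genoscreen.panel import Interval, PanelGene

__all__ = ["CnvEvent", "MatchResult", "match_event", "project_to_exons",
           "interval_overlap", "event_from_sv_fields"]


@dataclass
class CnvEvent:
    """A copy-number event at exon resolution.

    ``copy_number`` is an exact integer for observed events; expected
    amplifications may carry a lower bound via ``copy_number_min``.
    """

    gene: str
    type: Literal["deletion", "amplification"]
    exon_span: tuple[int, int] | None = None
    zygosity: str | None = None  # heterozygous | homozygous | n/a
    copy_number: int | None = None
    copy_number_min: int | None = None
    interval: Interval | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.type not in ("deletion", "amplification"):
            raise ValueError(f"unknown CNV type {self.type!r}")
        if self.exon_span is not None and self.exon_span[0] > self.exon_span[1]:
            raise ValueError(f"exon span {self.exon_span} start > end")
        if self.type == "deletion" and self.zygosity is None:
            raise ValueError("deletion events require zygosity")
        if self.type == "amplification" and (
            self.copy_number is None and self.copy_number_min is None
        ):
            raise ValueError("amplification events require a copy number")


@dataclass
class MatchResult:
    matched: bool
    reason: str

    def __bool__(self) -> bool:
        return self.matched


def match_event(observed: CnvEvent, expected: CnvEvent) -> MatchResult:
    """Exon-level match decision with a reason code on mismatch."""
    if observed.exon_span is None or expected.exon_span is None:
        raise ValueError(
            "events lack exon numbering; project intervals to exons first"
        )
    if observed.gene != expected.gene:
        return MatchResult(False, "gene")
    if observed.type != expected.type:
        return MatchResult(False, "type")
    if observed.exon_span != expected.exon_span:
        return MatchResult(
            False,
            f"exon_span observed {observed.exon_span} != expected {expected.exon_span}",
        )
    if expected.type == "deletion":
        if observed.zygosity != expected.zygosity:
            return MatchResult(False, "zygosity")
    else:
        bound = (
            expected.copy_number_min
            if expected.copy_number_min is not None
            else expected.copy_number
        )
        ocn = (
            observed.copy_number
            if observed.copy_number is not None
            else observed.copy_number_min
        )
        if ocn is None or ocn < bound:
            return MatchResult(False, f"copy_number {ocn} < expected >= {bound}")
    return MatchResult(True, "match")


def project_to_exons(
    interval: Interval, gene: PanelGene
) -> tuple[int, int] | None:
    """Transcript exon-number span of exons overlapped by >= 1 base.

    Returns ``None`` for an entirely intronic/flanking interval (an
    "intronic-only" event, not a match candidate).
    """
    if interval.chrom != gene.chrom:
        raise ValueError(
            f"interval on {interval.chrom} but {gene.symbol} is on {gene.chrom}"
        )
    numbers = [
        gene.exon_number(i)
        for i, (s, e) in enumerate(gene.exons)
        if interval.intersection_length(Interval(gene.chrom, s, e)) >= 1
    ]
    if not numbers:
        return None
    return (min(numbers), max(numbers))


def interval_overlap(
    a: Interval, b: Interval, mode: str = "jaccard"
) -> float:
    """Overlap fraction of two intervals.

    ``jaccard`` = |a∩b| / |a∪b|; ``reciprocal`` = min(|a∩b|/|a|, |a∩b|/|b|).
    Both are exposed because published overlap percentages rarely state
    their metric.  Different contigs → 0 with a warning.
    """
    if mode not in ("jaccard", "reciprocal"):
        raise ValueError(f"unknown overlap mode {mode!r}")
    if a.chrom != b.chrom:
        warnings.warn(
            f"interval_overlap on different contigs {a.chrom} vs {b.chrom}",
            stacklevel=2,
        )
        return 0.0
    inter = a.intersection_length(b)
    if inter == 0:
        return 0.0
    if mode == "jaccard":
        union = len(a) + len(b) - inter
        return inter / union
    return min(inter / len(a), inter / len(b))


def event_from_sv_fields(
    gene: str,
    svtype: str,
    chrom: str,
    start: int,
    end: int,
    copy_number: int | None = None,
    zygosity: str | None = None,
    sample_id: str = "",
) -> CnvEvent:
    """Build a CnvEvent from SV-style VCF fields (SVTYPE/END/CN)."""
    svtype = svtype.upper()
    if svtype == "DEL":
        etype = "deletion"
    elif svtype in ("DUP", "CNV", "AMP"):
        etype = "amplification"
    else:
        raise ValueError(f"unsupported SVTYPE {svtype!r}")
    return CnvEvent(
        gene=gene,
        type=etype,
        zygosity=zygosity if etype == "deletion" else None,
        copy_number=copy_number,
        interval=Interval(chrom, start, end),
        sample_id=sample_id,
    )
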