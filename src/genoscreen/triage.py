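"""Curation triage of classified variants.

Variants enter with two annotations: the tier assigned by an automated
ACMG/AMP five-tier classifier (B, LB, VUS, LP, P) and the ClinVar
interpretation for the associated condition.  A variant is targeted for
manual curation if the auto tier is P or LP, and/or the ClinVar
interpretation is P, LP, conflicting, or not-provided.  Unflagged variants
auto-accept their initial tier as final; flagged variants receive a final
tier from a curation-decisions file and remain ``pending`` until they do.

Note the deliberate distinction between ClinVar ``not_provided`` (a record
exists but carries no interpretation — triggers curation) and ``absent``
(the variant has no ClinVar record at all — does not trigger curation);
annotation aggregators often conflate the two.  PP5/BP6 evidence codes are
never consulted and the annotation schema omits them.

The transition matrix tallies initial (auto) against final tier across a
cohort, the shape used to audit auto-classifier performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from genoscreen.panel import PanelConfig
from genoscreen.variants import VariantCall

__all__ = [
    "TIERS",
    "CLINVAR_STATES",
    "ClassifiedVariant",
    "TransitionMatrix",
    "flag_for_curation",
    "apply_curation_decisions",
    "select_reportable",
    "tabulate_transitions",
    "load_annotations",
    "load_decisions",
]

TIERS = ("B", "LB", "VUS", "LP", "P")
CLINVAR_STATES = TIERS + ("conflicting", "not_provided", "absent")
_CURATION_CLINVAR = frozenset({"P", "LP", "conflicting", "not_provided"})
PENDING = "pending"


@dataclass
class ClassifiedVariant:
    """A variant joined to its automated and ClinVar tiers.

    ``risk_allele`` marks established risk alleles (e.g. APC p.Ile1307Lys)
    that are handled as Pathogenic for reporting purposes.
    """

    variant: VariantCall
    auto_tier: str
    clinvar_tier: str = "absent"
    final_tier: str = PENDING
    curation_flag: bool = False
    risk_allele: bool = False

    def __post_init__(self) -> None:
        if self.auto_tier not in TIERS:
            raise ValueError(f"unknown auto tier {self.auto_tier!r}")
        if self.clinvar_tier not in CLINVAR_STATES:
            raise ValueError(f"unknown ClinVar state {self.clinvar_tier!r}")
        if self.final_tier not in TIERS + (PENDING,):
            raise ValueError(f"unknown final tier {self.final_tier!r}")


def flag_for_curation(cv: ClassifiedVariant) -> ClassifiedVariant:
    """Apply the curation-triage rule.

    flag = auto in {P, LP}  OR  ClinVar in {P, LP, conflicting, not_provided}.
    Unflagged variants auto-accept: final tier = auto tier.  Idempotent.
    """
    flag = cv.auto_tier in ("P", "LP") or cv.clinvar_tier in _CURATION_CLINVAR
    final = cv.final_tier
    if not flag and final == PENDING:
        final = cv.auto_tier
    return replace(cv, curation_flag=flag, final_tier=final)


def apply_curation_decisions(
    variants: Iterable[ClassifiedVariant],
    decisions: Mapping[tuple[str, int, str, str], str],
) -> list[ClassifiedVariant]:
    """Resolve flagged variants from a (variant key -> final tier) mapping.

    Manual curation is a human step; this consumes its output.  Flagged
    variants without a decision stay ``pending`` and block report emission.
    """
    out = []
    for cv in variants:
        cv = flag_for_curation(cv)
        if cv.curation_flag:
            tier = decisions.get(cv.variant.key)
            if tier is not None:
                if tier not in TIERS:
                    raise ValueError(f"decision tier {tier!r} for {cv.variant.key}")
                cv = replace(cv, final_tier=tier)
        out.append(cv)
    return out


def select_reportable(
    variants: Iterable[ClassifiedVariant],
    panel: PanelConfig | None = None,
    include_risk_alleles: bool = True,
) -> list[ClassifiedVariant]:
    """Reportable results: final P/LP in panel genes, plus configured
    risk alleles (handled as Pathogenic)."""
    symbols = {g.symbol for g in panel.genes} if panel is not None else None
    out = []
    for cv in variants:
        if cv.final_tier == PENDING:
            raise ValueError(
                f"variant {cv.variant.key} is pending curation; cannot report"
            )
        if symbols is not None and cv.variant.gene not in symbols:
            continue
        if cv.final_tier in ("P", "LP"):
            out.append(cv)
        elif include_risk_alleles and cv.risk_allele:
            out.append(replace(cv, final_tier="P"))
    return out


@dataclass
class TransitionMatrix:
    """5x5 tally of (auto tier -> final tier) across a cohort."""

    counts: pd.DataFrame

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def col_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t")


def tabulate_transitions(
    variants: Sequence[ClassifiedVariant],
) -> TransitionMatrix:
    """Tally auto vs final tiers; errors if any variant is still pending."""
    pending = [cv.variant.key for cv in variants if cv.final_tier == PENDING]
    if pending:
        raise ValueError(f"{len(pending)} variants pending curation: {pending[:5]}")
    counts = pd.DataFrame(0, index=list(TIERS), columns=list(TIERS), dtype=int)
    for cv in variants:
        counts.loc[cv.auto_tier, cv.final_tier] += 1
    return TransitionMatrix(counts)


def load_annotations(path: str | Path) -> pd.DataFrame:
    """Annotations TSV: chrom, pos, ref, alt, auto_tier, clinvar_tier
    [, gene, risk_allele]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "auto_tier", "clinvar_tier"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotations file missing columns: {sorted(missing)}")
    return df


def load_decisions(path: str | Path) -> dict[tuple[str, int, str, str], str]:
    """Curation decisions TSV: chrom, pos, ref, alt, final_tier."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {
        (r.chrom, int(r.pos), r.ref, r.alt): r.final_tier
        for r in df.itertuples(index=False)
    }
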