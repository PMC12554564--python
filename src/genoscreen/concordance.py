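"""Gene-level concordance and diagnostic test statistics.

Two laboratories' results are compared per (sample, gene): a positive gene
match requires that *all* variants detected within the gene match between
the test and reference methods; a negative gene requires that neither
method reported a variant.  Anything else is discordant, with the
asymmetric difference attached so false-positive and false-negative
directions can be assigned.

From the resulting 2x2 confirmation table, sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), PPV = TP/(TP+FP) and NPV = TN/(TN+FN).
Sensitivity and specificity 95% CIs use the Clopper-Pearson exact
(beta-quantile) method; PPV/NPV CIs use the standard logit method — the
conventions of common diagnostic-test calculators.  A metric whose
denominator is zero is reported as undefined (None), never as 0.

The negative-gene denominator of a study (samples x genes covered, minus
positives) depends on per-sample panel composition and is therefore an
explicit input, never inferred silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from scipy.stats import beta, norm

__all__ = [
    "GeneResult",
    "Outcome",
    "ConcordanceTable",
    "Metric",
    "compare_gene",
    "build_table",
    "diagnostic_metrics",
    "clopper_pearson",
    "logit_interval",
]


@dataclass
class GeneResult:
    """One method's reported variants for one (sample, gene).

    Variant keys must be normalized (trimmed, left-aligned) before
    comparison; zygosity is part of the key only when both sides carry it.
    """

    sample_id: str
    gene: str
    variants: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.variants = frozenset(self.variants)


@dataclass
class Outcome:
    sample_id: str
    gene: str
    status: Literal["concordant_positive", "concordant_negative", "discordant"]
    test_only: frozenset = frozenset()
    ref_only: frozenset = frozenset()


def _strip_zygosity_if_one_sided(
    test: frozenset, ref: frozenset
) -> tuple[frozenset, frozenset]:
    """Drop the zygosity element of 5-tuple keys unless both sides have it."""

    def has_zyg(keys: frozenset) -> bool:
        return bool(keys) and all(len(k) == 5 for k in keys)

    if has_zyg(test) == has_zyg(ref):
        return test, ref
    return (
        frozenset(k[:4] for k in test),
        frozenset(k[:4] for k in ref),
    )


def compare_gene(test: GeneResult, ref: GeneResult) -> Outcome:
    """Gene-level match: identical non-empty sets are concordant positive,
    two empty sets concordant negative, anything else discordant."""
    if (test.sample_id, test.gene) != (ref.sample_id, ref.gene):
        raise ValueError(
            f"mismatched comparison: {test.sample_id}/{test.gene} vs "
            f"{ref.sample_id}/{ref.gene}"
        )
    tv, rv = _strip_zygosity_if_one_sided(test.variants, ref.variants)
    if tv == rv:
        status = "concordant_positive" if tv else "concordant_negative"
        return Outcome(test.sample_id, test.gene, status)
    return Outcome(
        test.sample_id,
        test.gene,
        "discordant",
        test_only=frozenset(tv - rv),
        ref_only=frozenset(rv - tv),
    )


@dataclass
class Metric:
    estimate: float | None
    lower: float | None = None
    upper: float | None = None

    def as_percent(self) -> str:
        """Report-text rendering at 2 decimals, e.g. '98.72%'."""
        if self.estimate is None:
            return "undefined"
        return f"{round(self.estimate * 100, 2):.2f}%"


@dataclass
class ConcordanceTable:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    sensitivity: Metric | None = None
    specificity: Metric | None = None
    ppv: Metric | None = None
    npv: Metric | None = None

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def build_table(outcomes: Iterable[Outcome]) -> ConcordanceTable:
    """Tally outcomes into a 2x2 table.

    A discordant outcome contributes a false positive when only the test
    method reported variants, a false negative when only the reference
    did, and one of each when both reported non-matching sets.
    """
    tp = fp = fn = tn = 0
    for o in outcomes:
        if o.status == "concordant_positive":
            tp += 1
        elif o.status == "concordant_negative":
            tn += 1
        else:
            if o.test_only and o.ref_only:
                fp += 1
                fn += 1
            elif o.test_only:
                fp += 1
            else:
                fn += 1
    return ConcordanceTable(tp=tp, fp=fp, fn=fn, tn=tn)


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial CI from beta quantiles; closed at 0 and 1."""
    if not 0 <= k <= n or n == 0:
        raise ValueError(f"invalid counts k={k}, n={n}")
    lower = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


def logit_interval(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Logit-transformed Wald interval for a proportion (PPV/NPV convention).

    Degenerate at k = 0 or k = n, where the exact interval is used instead.
    """
    if not 0 < k < n:
        return clopper_pearson(k, n, alpha)
    p = k / n
    z = float(norm.ppf(1 - alpha / 2))
    lo = math.log(p / (1 - p))
    se = math.sqrt(1 / k + 1 / (n - k))
    lo_l, lo_u = lo - z * se, lo + z * se
    expit = lambda x: 1 / (1 + math.exp(-x))  # noqa: E731
    return expit(lo_l), expit(lo_u)


def _metric(k: int, n: int, method, alpha: float) -> Metric | None:
    if n == 0:
        return Metric(None)
    lower, upper = method(k, n, alpha)
    return Metric(k / n, lower, upper)


def diagnostic_metrics(
    t: ConcordanceTable, alpha: float = 0.05
) -> ConcordanceTable:
    """Attach sensitivity/specificity (exact CIs) and PPV/NPV (logit CIs)."""
    t.sensitivity = _metric(t.tp, t.tp + t.fn, clopper_pearson, alpha)
    t.specificity = _metric(t.tn, t.tn + t.fp, clopper_pearson, alpha)
    t.ppv = _metric(t.tp, t.tp + t.fp, logit_interval, alpha)
    t.npv = _metric(t.tn, t.tn + t.fn, logit_interval, alpha)
    return t
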