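"""Gene-level comparison, 2x2 tables, and diagnostic metric CIs."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.stats import binom

from genoscreen.concordance import (
    ConcordanceTable,
    GeneResult,
    build_table,
    clopper_pearson,
    compare_gene,
    diagnostic_metrics,
)

V1 = ("chr17", 41_200_000, "A", "G")
V2 = ("chr17", 41_205_000, "C", "T")


def gr(variants, sample="s1", gene="BRCA1"):
    return GeneResult(sample, gene, frozenset(variants))


def test_gene_comparison_outcomes():
    assert compare_gene(gr([V1]), gr([V1])).status == "concordant_positive"
    assert compare_gene(gr([]), gr([])).status == "concordant_negative"
    fp = compare_gene(gr([V1]), gr([]))
    assert fp.status == "discordant" and fp.test_only == {V1} and not fp.ref_only
    partial = compare_gene(gr([V1, V2]), gr([V1]))
    assert partial.status == "discordant" and partial.test_only == {V2}


def test_gene_comparison_symmetric_up_to_direction():
    a = compare_gene(gr([V1]), gr([V2]))
    b = compare_gene(gr([V2]), gr([V1]))
    assert a.test_only == b.ref_only and a.ref_only == b.test_only


def test_mismatched_sample_or_gene_errors():
    with pytest.raises(ValueError):
        compare_gene(gr([], sample="s1"), gr([], sample="s2"))


def test_zygosity_dropped_when_only_one_side_has_it():
    with_zyg = gr([(*V1, "het")])
    without = gr([V1])
    assert compare_gene(with_zyg, without).status == "concordant_positive"
    # both sides carrying zygosity compare it
    assert (
        compare_gene(gr([(*V1, "het")]), gr([(*V1, "hom")])).status == "discordant"
    )


def _outcomes(n_pos, n_neg, n_fn=0, n_fp=0):
    out = []
    for i in range(n_pos):
        out.append(compare_gene(gr([V1], sample=f"p{i}"), gr([V1], sample=f"p{i}")))
    for i in range(n_neg):
        out.append(compare_gene(gr([], sample=f"n{i}"), gr([], sample=f"n{i}")))
    for i in range(n_fn):
        out.append(compare_gene(gr([], sample=f"fn{i}"), gr([V1], sample=f"fn{i}")))
    for i in range(n_fp):
        out.append(compare_gene(gr([V1], sample=f"fp{i}"), gr([], sample=f"fp{i}")))
    return out


def test_table_replays_screening_cohort_counts():
    t = build_table(_outcomes(17, 14_382))
    assert (t.tp, t.tn, t.fp, t.fn) == (17, 14_382, 0, 0)
    assert t.total == 14_399


def test_table_replays_exome_comparison_counts_and_metrics():
    t = diagnostic_metrics(build_table(_outcomes(77, 874, n_fn=1)))
    assert (t.tp, t.fn, t.tn, t.fp) == (77, 1, 874, 0)
    assert t.sensitivity.as_percent() == "98.72%"
    assert t.specificity.as_percent() == "100.00%"
    assert t.ppv.estimate == 1.0
    assert t.npv.estimate == pytest.approx(874 / 875)


def test_empty_table_metrics_undefined():
    t = diagnostic_metrics(build_table([]))
    assert t.total == 0
    assert t.sensitivity.estimate is None
    assert t.sensitivity.as_percent() == "undefined"


def test_perfect_sensitivity_lower_bound_small_n():
    """With 1/1 positives the exact interval is [alpha/2, 1]: the lower
    bound solves P(X >= 1 | n=1, p) = alpha/2, i.e. p = 0.025."""
    t = diagnostic_metrics(ConcordanceTable(tp=1, fn=0, fp=0, tn=0))
    assert t.sensitivity.estimate == 1.0
    assert t.sensitivity.lower == pytest.approx(0.025, abs=1e-12)
    assert t.sensitivity.upper == 1.0


def cp_oracle(k, n, alpha=0.05):
    """Invert the binomial CDF by root-finding — independent of the
    beta-quantile route used by the implementation."""
    lo = 0.0 if k == 0 else brentq(
        lambda p: 1 - binom.cdf(k - 1, n, p) - alpha / 2, 1e-12, 1 - 1e-12,
        xtol=1e-13,
    )
    hi = 1.0 if k == n else brentq(
        lambda p: binom.cdf(k, n, p) - alpha / 2, 1e-12, 1 - 1e-12, xtol=1e-13
    )
    return lo, hi


@pytest.mark.parametrize(
    "k,n", [(0, 5), (5, 5), (1, 1), (77, 78), (874, 874), (3, 10), (50, 100)]
)
def test_clopper_pearson_matches_binomial_inversion(k, n):
    got = clopper_pearson(k, n)
    want = cp_oracle(k, n)
    assert got[0] == pytest.approx(want[0], abs=1e-9)
    assert got[1] == pytest.approx(want[1], abs=1e-9)


@settings(max_examples=150, derandomize=True)
@given(n=st.integers(1, 500), data=st.data())
def test_interval_contains_estimate_and_shrinks_with_n(n, data):
    k = data.draw(st.integers(0, n))
    lo, hi = clopper_pearson(k, n)
    assert lo <= k / n <= hi
    # same proportion at 4x the sample size gives a narrower interval
    lo4, hi4 = clopper_pearson(4 * k, 4 * n)
    assert (hi4 - lo4) <= (hi - lo) + 1e-12
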