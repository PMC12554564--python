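"""VCF ingest, screening filters, and MNV decomposition."""

import numpy as np
import pytest

from genoscreen.panel import Interval, PanelConfig, PanelGene
from genoscreen.simulate import generate_mnv_case
from genoscreen.variants import (
    VariantCall,
    decompose_mnv,
    filter_vaf,
    read_vcf,
    restrict_to_regions,
    trim_alleles,
)

VCF_TEXT = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##contig=<ID=chr1>
##contig=<ID=chr17>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
chr17\t41200050\t.\tA\tG\t50\tPASS\t.\tGT:AD:DP\t0/1:15,15:30
chr1\t100\t.\tC\tT,G\t40\tPASS\t.\tGT:AD:DP\t1/2:2,14,16:32
chr1\t200\t.\tG\tA\t30\tPASS\t.\tGT:AD:DP\t./.:.:0
"""


@pytest.fixture()
def tiny_panel():
    return PanelConfig(
        genes=[
            PanelGene(
                "BRCA1", "chr17", "NM_TEST", [(41_200_000, 41_200_150)], "-"
            )
        ],
        flank_bases=100,
    )


def test_read_vcf_splits_multiallelics_and_tags_genes(tmp_path, tiny_panel):
    p = tmp_path / "s.vcf"
    p.write_text(VCF_TEXT)
    calls = list(read_vcf(p, tiny_panel))
    snv = [c for c in calls if c.chrom == "chr17"]
    assert len(snv) == 1 and snv[0].gene == "BRCA1" and snv[0].vaf == 0.5
    tri = sorted((c for c in calls if c.chrom == "chr1"), key=lambda c: c.alt)
    # triallelic record splits into two het observations with per-allele VAF
    assert [c.alt for c in tri] == ["G", "T"]
    assert tri[1].vaf == pytest.approx(14 / 32)
    assert tri[0].vaf == pytest.approx(16 / 32)
    assert all(c.gene is None for c in tri)
    # missing-GT record is skipped, not an error
    assert all(c.pos != 199 for c in calls)


@pytest.mark.parametrize(
    "vaf,expect_filtered",
    [(0.09, True), (0.10, False), (0.50, False)],
)
def test_vaf_filter_is_strictly_less_than_threshold(vaf, expect_filtered):
    v = VariantCall("chr1", 10, "A", "T", vaf=vaf)
    out = filter_vaf(v, 0.10)
    assert out.filtered is expect_filtered
    if expect_filtered:
        assert out.filter_reason == "low_vaf"


def _regions():
    exons = [(i * 1000, i * 1000 + 100) for i in range(1, 16)]
    cfg = PanelConfig(
        genes=[PanelGene("PMS2", "chr7", "NM_TEST", exons, "+")],
        flank_bases=500,
    )
    return cfg.regions()


def test_region_restriction_reason_codes():
    regions = _regions()
    inside_excluded = VariantCall("chr7", 12_050, "A", "T")  # exon 12
    inside_ok = VariantCall("chr7", 5_050, "A", "T")  # exon 5
    outside = VariantCall("chr3", 5_050, "A", "T")
    assert restrict_to_regions(inside_excluded, regions).filter_reason == "excluded_region"
    kept = restrict_to_regions(inside_ok, regions)
    assert not kept.filtered and kept.gene == "PMS2"
    assert restrict_to_regions(outside, regions).filter_reason == "off_panel"


def test_boundary_straddling_deletion_counts_as_on_panel():
    regions = _regions()
    # region starts at 500; deletion [495, 505) overlaps by 5 bases
    straddler = VariantCall("chr7", 495, "AAAAAAAAAA", "A")
    assert not restrict_to_regions(straddler, regions).filtered


def test_filters_commute():
    regions = _regions()
    for v in [
        VariantCall("chr7", 5_050, "A", "T", vaf=0.05),
        VariantCall("chr7", 12_050, "A", "T", vaf=0.5),
        VariantCall("chr3", 10, "A", "T", vaf=0.5),
    ]:
        a = restrict_to_regions(filter_vaf(v, 0.1), regions)
        b = filter_vaf(restrict_to_regions(v, regions), 0.1)
        assert a.filtered == b.filtered


def test_trim_alleles_minimal_leftmost():
    assert trim_alleles(100, "ATG", "ATC") == (102, "G", "C")
    assert trim_alleles(100, "CTT", "C") == (100, "CTT", "C")
    assert trim_alleles(100, "GCAT", "GAT") == (100, "GC", "G")


@pytest.mark.parametrize(
    "ref,alt,expected",
    [
        ("AG", "TC", [(0, "A", "T"), (1, "G", "C")]),
        ("AG", "AC", [(1, "G", "C")]),
        ("ATG", "CTC", [(0, "A", "C"), (2, "G", "C")]),
    ],
)
def test_mnv_decomposition_positionwise(ref, alt, expected):
    v = VariantCall("chr1", 500, ref, alt, genotype="het")
    res = decompose_mnv(v)
    assert res.decomposed
    got = [(c.pos - 500, c.ref, c.alt) for c in res.components]
    assert got == expected
    assert all(c.genotype == v.genotype for c in res.components)


def test_length_changing_variant_not_decomposed():
    v = VariantCall("chr1", 500, "ATG", "A")
    res = decompose_mnv(v)
    assert not res.decomposed and res.components == [v]


def test_mnv_decomposition_conserves_sequence():
    """Applying all component SNVs to ref reproduces alt, on 10,000
    random same-length substitutions."""
    rng = np.random.default_rng(20_240_101)
    bases = np.array(list("ACGT"))
    for _ in range(10_000):
        n = int(rng.integers(2, 7))
        ref = "".join(rng.choice(bases, n))
        alt = "".join(rng.choice(bases, n))
        if ref == alt:
            alt = alt[:-1] + ("A" if alt[-1] != "A" else "C")
        v = VariantCall("chr1", int(rng.integers(0, 10**6)), ref, alt)
        res = decompose_mnv(v)
        rebuilt = list(ref)
        for c in res.components:
            off = c.pos - v.pos
            assert rebuilt[off] == c.ref
            rebuilt[off] = c.alt
        assert "".join(rebuilt) == alt


def test_mnv_fixture_components_are_common_snvs():
    parent, af_table = generate_mnv_case()
    res = decompose_mnv(parent, af_table)
    assert len(res.components) == 2
    assert all(af > 0.05 for af in res.component_afs)
    # with an empty table the component frequencies fall to zero
    assert decompose_mnv(parent, {}).component_afs == [0.0, 0.0]
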