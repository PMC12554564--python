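"""Star-allele diplotyping: examples, brute-force oracle, phenotypes."""

from itertools import combinations_with_replacement, product

import pytest

from genoscreen import pgx as P

S2 = ("chr10", 96541615, "G", "A")
S3 = ("chr10", 96540409, "G", "A")
S4 = ("chr10", 96522462, "A", "G")   # *4 core (also in *4B)
S17 = ("chr10", 96521656, "C", "T")  # *17 promoter (also in *4B)
S8 = ("chr10", 96535209, "T", "C")


def geno(defs, **dosage_by_site):
    d = {s: 0 for s in defs.sites}
    d.update(dosage_by_site)
    return P.SiteGenotypes(defs.gene, "test", d)


def geno_at(defs, sites_dosages):
    d = {s: 0 for s in defs.sites}
    d.update(sites_dosages)
    return P.SiteGenotypes(defs.gene, "test", d)


class TestDiplotypeExamples:
    def test_all_reference_sites_call_default(self, definitions):
        dip = P.call_diplotype(geno(definitions["CYP2C19"]), definitions["CYP2C19"])
        assert dip.label == "*1/*1" and not dip.ambiguous

    def test_hom_alt_single_site(self, definitions):
        dip = P.call_diplotype(
            geno_at(definitions["CYP2C19"], {S2: 2}), definitions["CYP2C19"]
        )
        assert dip.label == "*2/*2"

    def test_ambiguous_pair_resolves_to_two_named_alleles(self, definitions):
        """Het at the *4-core site plus het at the *17 promoter site is
        consistent with both *4A/*17 and *4B/*1; the tie-break prefers the
        pair with more non-default alleles and records the alternative."""
        dip = P.call_diplotype(
            geno_at(definitions["CYP2C19"], {S4: 1, S17: 1}),
            definitions["CYP2C19"],
        )
        assert dip.label == "*4A/*17"
        assert dip.ambiguous
        assert ("*1", "*4B") in dip.alternatives

    def test_three_het_sites_force_unique_suballele_partition(self, definitions):
        """Het at *2 + *4-core + *17 sites: the only partition in which
        both haplotypes are exactly named alleles is *2 / *4B."""
        dip = P.call_diplotype(
            geno_at(definitions["CYP2C19"], {S2: 1, S4: 1, S17: 1}),
            definitions["CYP2C19"],
        )
        assert dip.label == "*2/*4B"
        assert not dip.ambiguous

    def test_no_call_site_gives_unresolved_not_default(self, definitions):
        dip = P.call_diplotype(
            geno_at(definitions["CYP2C19"], {S2: None}), definitions["CYP2C19"]
        )
        assert not dip.resolved and dip.label == "unresolved"

    def test_inconsistent_genotypes_unresolved(self, definitions):
        # three het sites across *2/*3/*8: no 2-haplotype partition of
        # exactly-named alleles exists
        dip = P.call_diplotype(
            geno_at(definitions["CYP2C19"], {S2: 1, S3: 1, S8: 1}),
            definitions["CYP2C19"],
        )
        assert not dip.resolved
        assert dip.reason is not None

    def test_genotype_style_locus_reports_ref_first(self, definitions):
        defs = definitions["VKORC1"]
        site = defs.sites[0]
        assert P.call_diplotype(geno_at(defs, {site: 0}), defs).label == "GG"
        assert P.call_diplotype(geno_at(defs, {site: 1}), defs).label == "GA"
        assert P.call_diplotype(geno_at(defs, {site: 2}), defs).label == "AA"


def brute_force_pairs(dosages, defs):
    """Independent oracle: enumerate unordered pairs of (named allele or
    default) and keep those whose summed per-site dosage equals the
    observation."""
    candidates = {a.allele: a.defining_variants for a in defs.alleles}
    candidates[defs.default_allele] = frozenset()
    valid = set()
    for n1, n2 in combinations_with_replacement(sorted(candidates), 2):
        ok = all(
            (site in candidates[n1]) + (site in candidates[n2]) == d
            for site, d in dosages.items()
        )
        if ok:
            valid.add(tuple(sorted((n1, n2))))
    return valid


def test_caller_matches_bruteforce_enumeration_exhaustively(definitions):
    """On a 5-site CYP2C19 subset, every genotype vector in {0,1,2}^5
    yields exactly the pairs the brute-force oracle finds, and the selected
    pair maximizes the non-default allele count."""
    full = definitions["CYP2C19"]
    keep = {"*2", "*3", "*4A", "*4B", "*17"}
    defs = P.GeneDefinitions(
        "CYP2C19",
        [a for a in full.alleles if a.allele in keep],
        style="star",
    )
    sites = defs.sites
    assert len(sites) == 4  # *4B shares its sites with *4A and *17
    for vector in product((0, 1, 2), repeat=len(sites)):
        dosages = dict(zip(sites, vector))
        dip = P.call_diplotype(
            P.SiteGenotypes("CYP2C19", "x", dict(dosages)), defs
        )
        expected = brute_force_pairs(dosages, defs)
        if not expected:
            assert not dip.resolved
            continue
        assert dip.resolved
        got = {tuple(sorted((dip.allele_1, dip.allele_2)))}
        got |= {tuple(sorted(p)) for p in dip.alternatives}
        assert got == expected
        n_nondefault = sum(
            a != "*1" for a in (dip.allele_1, dip.allele_2)
        )
        best_possible = max(
            sum(a != "*1" for a in pair) for pair in expected
        )
        assert n_nondefault == best_possible
        assert dip.ambiguous == (len(expected) > 1)


def test_caller_matches_oracle_on_six_site_cyp2c9(definitions):
    full = definitions["CYP2C9"]
    sites = full.sites
    assert len(sites) == 6
    for vector in product((0, 1, 2), repeat=6):
        dosages = dict(zip(sites, vector))
        dip = P.call_diplotype(P.SiteGenotypes("CYP2C9", "x", dict(dosages)), full)
        expected = brute_force_pairs(dosages, full)
        if not expected:
            assert not dip.resolved
        else:
            got = {tuple(sorted((dip.allele_1, dip.allele_2)))}
            got |= {tuple(sorted(p)) for p in dip.alternatives}
            assert got == expected


def test_calling_invariant_to_record_order(definitions):
    defs = definitions["CYP2C19"]
    from genoscreen.variants import VariantCall

    calls = [
        VariantCall("chr10", S2[1], "G", "A", genotype="het"),
        VariantCall("chr10", S17[1], "C", "T", genotype="het"),
        VariantCall("chr10", S4[1], "A", "G", genotype="het"),
    ]
    labels = set()
    for order in (calls, calls[::-1], [calls[1], calls[2], calls[0]]):
        g = P.genotype_sites(order, defs)
        labels.add(P.call_diplotype(g, defs).label)
    assert labels == {"*2/*4B"}


def test_mismatched_alt_is_flagged_and_not_counted(definitions):
    from genoscreen.variants import VariantCall

    defs = definitions["CYP2C19"]
    wrong_alt = VariantCall("chr10", S2[1], "G", "C", genotype="het")
    g = P.genotype_sites([wrong_alt], defs)
    assert g.flagged == [wrong_alt]
    assert g.dosages[S2] == 0


class TestPhenotypes:
    @pytest.mark.parametrize(
        "gene,diplotype,expected",
        [
            ("CYP2C19", "*1/*1", "Normal metabolizer"),
            ("CYP2C19", "*17/*17", "Ultrarapid metabolizer"),
            ("CYP2C19", "*1/*17", "Rapid metabolizer"),
            ("CYP2C19", "*2/*17", "Intermediate metabolizer"),
            ("CYP2C19", "*2/*2", "Poor metabolizer"),
            ("CYP2C19", "*2/*4B", "Poor metabolizer"),
            ("CYP2C19", "*4A/*17", "Intermediate metabolizer"),
            ("CYP2C9", "*1/*3", "Intermediate metabolizer"),
            ("CYP2C9", "*2/*2", "Poor metabolizer"),
            ("CYP4F2", "*1/*3", "Warfarin resistant"),
            ("CYP4F2", "*1/*1", "Normal warfarin sensitivity"),
            ("VKORC1", "GA", "Warfarin sensitive"),
            ("VKORC1", "GG", "Normal warfarin sensitivity"),
            ("rs12777823", "AA", "Warfarin sensitive"),
        ],
    )
    def test_mapping(self, gene, diplotype, expected, functions):
        assert P.phenotype_for_label(gene, diplotype, functions) == expected

    def test_unknown_function_is_indeterminate(self, definitions):
        dip = P.DiplotypeCall("CYP2C19", "*99", "*1")
        assert P.map_phenotype(dip, {("CYP2C19", "*1"): "normal"}).phenotype == (
            "Indeterminate"
        )

    def test_unresolved_diplotype_is_indeterminate(self):
        dip = P.DiplotypeCall("CYP2C19", None, None, resolved=False)
        assert P.map_phenotype(dip, {}).phenotype == "Indeterminate"


def test_core_allele_collapses_suballeles():
    assert P.core_allele("*4A") == "*4" == P.core_allele("*4B")
    assert P.core_allele("*17") == "*17"
    assert P.core_allele("A") == "A"


def test_summarize_cohort_percentages(cohort_distribution, functions):
    calls = []
    i = 0
    for gene, dip, n in cohort_distribution:
        if gene != "CYP2C19":
            continue
        for _ in range(n):
            calls.append(
                P.PhenotypeCall(
                    gene, dip, P.phenotype_for_label(gene, dip, functions), f"s{i}"
                )
            )
            i += 1
    df = P.summarize_cohort(calls)
    by_cat = dict(zip(df["category"], df["percent"]))
    assert by_cat["Intermediate metabolizer"] == 27.1
    assert sum(df["n"]) == 188
    assert abs(df["percent"].sum() - 100.0) < 0.3  # rounding only

    single = P.summarize_cohort(
        [P.PhenotypeCall("CYP2C9", "*1/*1", "Normal metabolizer", "only")]
    )
    assert list(single["percent"]) == [100.0]


def test_duplicate_sample_gene_pair_rejected():
    calls = [
        P.PhenotypeCall("CYP2C19", "*1/*1", "Normal metabolizer", "s1"),
        P.PhenotypeCall("CYP2C19", "*1/*2", "Intermediate metabolizer", "s1"),
    ]
    with pytest.raises(ValueError, match="duplicate"):
        P.summarize_cohort(calls)
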