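import pytest

from genoscreen import pgx as pgx_mod
from genoscreen.simulate import demo_panel


@pytest.fixture(scope="session")
def definitions():
    return pgx_mod.load_default_definitions()


@pytest.fixture(scope="session")
def functions():
    return pgx_mod.load_default_functions()


@pytest.fixture(scope="session")
def cohort_distribution():
    return pgx_mod.load_cohort_distribution()


@pytest.fixture()
def panel():
    return demo_panel()


def hom_ref_genotypes(defs, **overrides):
    """SiteGenotypes with every defining site hom-ref, then overrides.

    Overrides are keyed by rsid-independent (pos0, alt) shorthand via full
    site keys for clarity in tests.
    """
    dosages = {s: 0 for s in defs.sites}
    dosages.update(overrides)
    return pgx_mod.SiteGenotypes(defs.gene, "test", dosages)
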