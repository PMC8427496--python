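import pytest

import afpanel as ap


@pytest.fixture(scope="session")
def panel():
    return ap.load_panel()


@pytest.fixture(scope="session")
def cohort(panel):
    return ap.paper_fixture(panel)


@pytest.fixture(scope="session")
def filtered(cohort, panel):
    """The constructed cohort after reporting rules and rarity filter."""
    table = ap.apply_reporting_rules(cohort.variant_table(panel), panel)
    return ap.rare_filter(table, 0.001)


@pytest.fixture(scope="session")
def classified(filtered, panel):
    return ap.classify_table(filtered, panel)


@pytest.fixture(scope="session")
def assignments(cohort, classified, panel):
    return ap.assign_groups(cohort.participants, classified, panel)
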