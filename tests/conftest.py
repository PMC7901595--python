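import pytest

from dpconcord.data_model import load_items_fixture, load_table1
from dpconcord.synthetic_study import table1_design


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def fixture_items():
    items, design = load_items_fixture()
    return items


@pytest.fixture(scope="session")
def fixture_design():
    _, design = load_items_fixture()
    return design


@pytest.fixture(scope="session")
def canonical_design():
    return table1_design()


@pytest.fixture(scope="session")
def table1_posterior(canonical_design):
    """Full-scale fit of the hierarchical model to the reconstructed dataset.

    Session-scoped: shared by the posterior-summary and predictive tests.
    """
    from dpconcord.hier_model import FitConfig, fit
    from dpconcord.synthetic_study import table1_items

    return fit(table1_items(), canonical_design, FitConfig(seed=7))
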