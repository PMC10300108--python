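import pytest

from spinescreen import policies


@pytest.fixture(scope="session")
def agile_suite():
    """The shipped crisp screening suite (amplitude 2±0.5, width 100±10)."""
    return policies.load_agile_worked_example()


@pytest.fixture(scope="session")
def agile_xml():
    return policies.agile_worked_example_xml()


@pytest.fixture(scope="session")
def fuzzy_policy():
    """The shipped Mamdani reference policy."""
    return policies.load_fuzzy_reference()


@pytest.fixture(scope="session")
def fuzzy_xml():
    return policies.fuzzy_reference_xml()
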