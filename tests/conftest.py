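import pytest

from vpanel.fixtures import gen_case_fixture


@pytest.fixture(scope="session")
def case_bundle():
    return gen_case_fixture()


@pytest.fixture(scope="session")
def case_paths(case_bundle, tmp_path_factory):
    """Case bundle written to disk (VCF reading needs real files)."""
    return case_bundle.write(tmp_path_factory.mktemp("case"))


@pytest.fixture(scope="session")
def case_ontology(case_bundle):
    return case_bundle.ontology()


@pytest.fixture(scope="session")
def case_store(case_bundle):
    return case_bundle.store()
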