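import pytest

from flypheno import classify, generate_lethal_phase_terms
from flypheno.fixtures import (
    default_imports,
    default_stage_chain,
    make_named_fixtures,
)


@pytest.fixture(scope="session")
def named_docs():
    return make_named_fixtures()


@pytest.fixture(scope="session")
def imports():
    return default_imports()


@pytest.fixture(scope="session")
def dpo(named_docs):
    return named_docs["mini-dpo"]


@pytest.fixture(scope="session")
def dpo_hierarchy(dpo, imports):
    return classify(dpo, imports)


@pytest.fixture(scope="session")
def chain():
    return default_stage_chain()


@pytest.fixture(scope="session")
def lethal_terms(chain):
    return generate_lethal_phase_terms(chain)
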