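import io

import pytest

from aoplink.ontology import parse_obo
from aoplink.synthetic import SyntheticConfig, generate_bundle


@pytest.fixture(scope="session")
def small_config():
    """A reduced synthetic study: fast enough for unit tests, structurally
    identical to the default conditions."""
    return SyntheticConfig(seed=3, n_terms=80, n_genes=400, n_events=6)


@pytest.fixture(scope="session")
def bundle(small_config):
    return generate_bundle(small_config, n_conditions=2)


@pytest.fixture(scope="session")
def graph(bundle):
    return parse_obo(io.StringIO(bundle["obo_text"]))


@pytest.fixture(scope="session")
def annotation(bundle, graph):
    return bundle["annotation"].propagate(graph)
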