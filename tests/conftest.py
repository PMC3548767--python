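import pytest

from protinfer import build_graph, classify
from protinfer.fixtures import fixture_F1, fixture_MR1


@pytest.fixture
def f1_records():
    return fixture_F1()


@pytest.fixture
def f1_graph(f1_records):
    return build_graph(f1_records)


@pytest.fixture
def f1_result(f1_graph):
    return classify(f1_graph)


@pytest.fixture
def mr1_records():
    return fixture_MR1()
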