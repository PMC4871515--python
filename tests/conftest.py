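import pytest

from mstmc.magraph import MAGraph, ScaleSubsystem
from mstmc.registry import default_registry


@pytest.fixture
def registry():
    return default_registry()


@pytest.fixture
def single_vertex_graph():
    return MAGraph(ScaleSubsystem("Scale", "Sub"))


@pytest.fixture
def chain_graph():
    """The three-vertex growth-media -> microorganism -> network chain."""
    from mstmc.fixtures import toy_ma_graph
    return toy_ma_graph()


@pytest.fixture
def organism_graph():
    from mstmc.fixtures import organ_ma_graph
    return organ_ma_graph()
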