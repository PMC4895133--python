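import numpy as np
import pytest

import connectopo as ct


@pytest.fixture
def triangle():
    return ct.Graph.from_edges(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def path3():
    return ct.Graph.from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture
def star5():
    return ct.Graph.from_edges(6, [(0, i) for i in range(1, 6)])


@pytest.fixture(scope="session")
def gwb_spec():
    """Generalized-Weibull tail with connectome-like shape parameters."""
    return ct.DegreeModelSpec("GWB", 0, [],
                              {"alpha": 0.358, "beta": 0.426,
                               "gamma": 141.72})


@pytest.fixture(scope="session")
def gwb_hist(gwb_spec):
    """20k degrees sampled from the GWB spec (shared across tests)."""
    degrees = ct.sample_degree_sequence(gwb_spec, 20_000, seed=424242)
    return ct.DegreeHistogram.from_degrees(degrees)


@pytest.fixture(scope="session")
def er_graph_small():
    return ct.largest_connected_component(
        ct.erdos_renyi_graph(2000, 10_000, seed=99))
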