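import numpy as np
import pytest

from hotnets import Event, NodeTable, TemporalHypergraph, hyperlink


def make_net(events, n_nodes=None, T=None, dt=1.0, dt_unit="s"):
    """Build a network from (node-iterable, t) pairs with dense int labels."""
    evs = [Event(hyperlink(nodes), t) for nodes, t in events]
    if n_nodes is None:
        n_nodes = 1 + max(v for ev in evs for v in ev.hyperlink) if evs else 0
    if T is None:
        T = 1 + max(ev.t for ev in evs) if evs else 0
    nodes = NodeTable(tuple(str(i) for i in range(n_nodes)))
    return TemporalHypergraph(nodes, tuple(evs), T=T, dt=dt, dt_unit=dt_unit)


def random_net(rng, n_nodes=20, n_events=40, T=50, orders=(2, 3, 4)):
    """Random small network for oracle comparisons."""
    evs = set()
    while len(evs) < n_events:
        d = int(rng.choice(orders))
        nodes = rng.choice(n_nodes, size=d, replace=False)
        evs.add(Event(hyperlink(int(v) for v in nodes), int(rng.integers(T))))
    nodes = NodeTable(tuple(str(i) for i in range(n_nodes)))
    return TemporalHypergraph(nodes, tuple(sorted(evs)), T=T)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def mixed_net():
    """Small mixed-order network used across modules."""
    return make_net([
        ((0, 1, 2), 0),
        ((0, 1, 2), 4),
        ((0, 1), 1),
        ((2, 3), 2),
        ((3, 4), 2),
        ((3, 4), 6),
        ((0, 1, 3, 4), 5),
    ])
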