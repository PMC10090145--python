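"""Building higher-order networks from pairwise contacts, and preprocessing.

Face-to-face contact data arrive as dyadic records; group interactions are
recovered by *clique promotion*: at every time step, each maximal clique of
the simultaneous-contact graph becomes one event of that clique's size, and
its sub-cliques are dropped.  The module also implements the two standard
preprocessing steps (restriction to the largest connected component of the
aggregated graph; removal of outlying network-wide inactivity gaps) and the
missing-link completion robustness variant, which patches near-cliques of
size > 3 that miss exactly one contact before re-promotion.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .core import (
    Event,
    NodeTable,
    TemporalHypergraph,
    aggregate_pairwise,
    hyperlink,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GapRule",
    "PreprocessReport",
    "promote_cliques",
    "complete_missing_links",
    "restrict_to_lcc",
    "remove_inactivity_gaps",
]


@dataclass(frozen=True)
class GapRule:
    """Outlier rule for network-wide inactivity gaps.

    ``tukey``: a gap is removed when longer than Q3 + parameter * IQR of the
    gap-length distribution (robust fence; default multiplier 3).
    ``quantile``: longer than the ``parameter`` quantile of gap lengths.
    ``fixed``: longer than ``parameter`` steps.
    """

    method: str = "tukey"
    parameter: float = 3.0

    def __post_init__(self) -> None:
        if self.method not in ("tukey", "quantile", "fixed"):
            raise ValueError(f"unknown gap rule {self.method!r}")
        if self.method == "quantile" and not 0 < self.parameter < 1:
            raise ValueError("quantile parameter must be in (0, 1)")
        if self.parameter <= 0:
            raise ValueError("gap-rule parameter must be positive")

    def threshold(self, gap_lengths: list[int]) -> float:
        """Length above which (strictly) a zero-activity run is removed."""
        if self.method == "fixed":
            return self.parameter
        if not gap_lengths:
            return float("inf")
        arr = np.asarray(gap_lengths, dtype=float)
        if self.method == "quantile":
            return float(np.quantile(arr, self.parameter))
        q1, q3 = np.quantile(arr, [0.25, 0.75])
        return float(q3 + self.parameter * (q3 - q1))


@dataclass(frozen=True)
class PreprocessReport:
    nodes_removed: int = 0
    gaps_removed: tuple[tuple[int, int], ...] = ()  # (start step, length)
    steps_removed: int = 0
    T_before: int = 0
    T_after: int = 0


def _events_by_step(net: TemporalHypergraph) -> dict[int, list[Event]]:
    by_t: dict[int, list[Event]] = defaultdict(list)
    for ev in net.events:
        by_t[ev.t].append(ev)
    return by_t


def promote_cliques(net: TemporalHypergraph) -> TemporalHypergraph:
    """Promote each per-step maximal contact clique to one event of its size.

    Requires an order-2-only network.  A contact pair that is itself maximal
    stays an order-2 event; a pair covered by a larger simultaneous clique is
    absorbed into that clique's event.  Overlapping maximal cliques at the
    same step each yield an event.
    """
    if any(ev.order != 2 for ev in net.events):
        raise ValueError("promote_cliques requires an order-2-only network")
    out: list[Event] = []
    for t, evs in _events_by_step(net).items():
        g = nx.Graph(ev.hyperlink for ev in evs)
        for clique in nx.find_cliques(g):
            out.append(Event(hyperlink(clique), t))
    return net.with_events(sorted(out))


def complete_missing_links(
    net: TemporalHypergraph,
) -> tuple[TemporalHypergraph, int]:
    """Add, per step, the missing edge of every near-clique of size >= 4.

    A near-clique is a node subset whose induced simultaneous-contact graph
    is complete minus exactly one edge.  Any near-clique containing a given
    non-adjacent pair (u, v) misses exactly that pair, so the scan runs over
    non-edges: (u, v) is patched iff at least two of its common neighbours
    are themselves adjacent (giving a near-clique of size >= 4).  Single
    pass per step; the output feeds :func:`promote_cliques`.
    """
    if any(ev.order != 2 for ev in net.events):
        raise ValueError("complete_missing_links requires an order-2-only network")
    out: list[Event] = list(net.events)
    n_added = 0
    for t, evs in _events_by_step(net).items():
        g = nx.Graph(ev.hyperlink for ev in evs)
        added: set[tuple[int, int]] = set()
        for u in g:
            two_hop = {w for nb in g[u] for w in g[nb]} - set(g[u]) - {u}
            for v in two_hop:
                if u >= v or (min(u, v), max(u, v)) in added:
                    continue
                common = list(set(g[u]) & set(g[v]))
                if len(common) < 2:
                    continue
                if any(g.has_edge(a, b) for a, b in itertools.combinations(common, 2)):
                    added.add((u, v))
        for u, v in sorted(added):
            out.append(Event(hyperlink((u, v)), t))
            n_added += 1
    return net.with_events(sorted(out)), n_added


def restrict_to_lcc(
    net: TemporalHypergraph,
) -> tuple[TemporalHypergraph, PreprocessReport]:
    """Drop nodes outside the largest component of the aggregated graph ``G``.

    Every event touches nodes of a single component (its node set is a
    clique in ``G``), so events of other components are removed wholesale.
    Ties between equal-size components go to the one containing the smallest
    original node id.  The node table is re-densified.
    """
    if not net.events:
        return net, PreprocessReport(T_before=net.T, T_after=net.T)
    g = aggregate_pairwise(net).to_networkx()
    comps = list(nx.connected_components(g))
    comps.sort(key=lambda c: (-len(c), min(c)))
    keep = comps[0]
    kept_ids = sorted(keep)
    remap = {old: new for new, old in enumerate(kept_ids)}
    nodes = NodeTable(tuple(net.nodes.label(i) for i in kept_ids))
    events = [
        Event(hyperlink(remap[v] for v in ev.hyperlink), ev.t)
        for ev in net.events
        if ev.hyperlink[0] in keep
    ]
    report = PreprocessReport(
        nodes_removed=net.n_nodes - len(kept_ids),
        T_before=net.T,
        T_after=net.T,
    )
    out = TemporalHypergraph(nodes, tuple(sorted(events)), T=net.T, dt=net.dt,
                             dt_unit=net.dt_unit, contact_type=net.contact_type)
    return out, report


def remove_inactivity_gaps(
    net: TemporalHypergraph,
    rule: GapRule = GapRule(),
    collapse_to: int = 0,
) -> tuple[TemporalHypergraph, PreprocessReport]:
    """Delete outlying zero-activity runs from the network-wide clock.

    The network-wide activity series counts events per step; maximal runs of
    zero-activity steps whose length is an outlier under ``rule`` are
    collapsed to ``collapse_to`` steps (0 by default: the period is removed
    entirely) and all later timestamps shift left accordingly.  The event
    multiset is unchanged; inter-event times not spanning a removed gap are
    preserved.
    """
    if not net.events:
        return net, PreprocessReport(T_before=net.T, T_after=net.T)
    active = np.zeros(net.T, dtype=bool)
    for ev in net.events:
        active[ev.t] = True
    # maximal zero runs as (start, length)
    runs: list[tuple[int, int]] = []
    start = None
    for t in range(net.T):
        if not active[t]:
            if start is None:
                start = t
        elif start is not None:
            runs.append((start, t - start))
            start = None
    if start is not None:
        runs.append((start, net.T - start))
    thr = rule.threshold([length for _, length in runs])
    removed = [(s, length) for s, length in runs if length > thr]
    if not removed:
        return net, PreprocessReport(T_before=net.T, T_after=net.T)
    cut = sum(length - collapse_to for _, length in removed)
    shift = np.zeros(net.T, dtype=np.int64)
    for s, length in removed:
        shift[s + length:] += length - collapse_to
    events = tuple(sorted(
        Event(ev.hyperlink, ev.t - int(shift[ev.t])) for ev in net.events))
    T_after = net.T - cut
    report = PreprocessReport(
        gaps_removed=tuple(removed),
        steps_removed=cut,
        T_before=net.T,
        T_after=T_after,
    )
    out = TemporalHypergraph(net.nodes, events, T=T_after, dt=net.dt,
                             dt_unit=net.dt_unit, contact_type=net.contact_type)
    return out, report
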