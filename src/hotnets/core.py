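"""Core data model for higher-order evolving networks (temporal hypergraphs).

A higher-order evolving network records *events*: activations of a
*hyperlink* (a set of ``d >= 2`` nodes) at a discrete time step.  The module
provides the in-memory containers, readers/writers for two plain-text
dialects (the SocioPatterns-style ``tij`` contact list and a native
hyperevent TSV) and the static aggregations used throughout the package:

* the unweighted pairwise aggregated graph ``G`` (node pairs that ever
  co-occurred in an event) on which hop counts are measured, and
* the weighted aggregated hypergraph ``H`` whose weights count activations.

Nodes carry opaque external labels; internally they are dense integer ids.
Hyperlinks are canonicalized as strictly increasing tuples of dense ids, so
identity is the node *set*.
"""

from __future__ import annotations

import itertools
import logging
import math
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Hyperlink",
    "hyperlink",
    "Event",
    "NodeTable",
    "TemporalHypergraph",
    "ActivitySeries",
    "AggregatedPairwiseGraph",
    "AggregatedHypergraph",
    "OrderCensus",
    "ParseError",
    "read_contact_list",
    "read_hyperevent_list",
    "write_hyperevent_list",
    "aggregate_pairwise",
    "aggregate_higher_order",
    "activity_series",
    "order_census",
    "descriptives",
]

#: A hyperlink is a strictly increasing tuple of dense node ids (set identity).
Hyperlink = tuple[int, ...]


class ParseError(ValueError):
    """Malformed line in a contact or hyperevent file."""


def hyperlink(nodes: Iterable[int]) -> Hyperlink:
    """Canonicalize a node collection into a hyperlink tuple.

    Sorts the ids and validates that there are at least two distinct nodes
    and no repeats.
    """
    tup = tuple(sorted(nodes))
    if len(tup) < 2:
        raise ValueError(f"hyperlink needs >= 2 nodes, got {tup!r}")
    if any(a == b for a, b in zip(tup, tup[1:])):
        raise ValueError(f"repeated node in hyperlink {tup!r}")
    return tup


class Event(NamedTuple):
    """Activation of a hyperlink at an integer time step."""

    hyperlink: Hyperlink
    t: int

    @property
    def order(self) -> int:
        return len(self.hyperlink)


@dataclass(frozen=True)
class NodeTable:
    """Bijective mapping between external labels and dense ids ``0..n-1``."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate node labels")

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "NodeTable":
        """Build from labels in first-appearance order (duplicates collapse)."""
        seen: dict[str, None] = {}
        for lab in labels:
            seen.setdefault(str(lab))
        return cls(tuple(seen))

    @property
    def index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.labels)}

    def id(self, label: str) -> int:
        return self.index[label]

    def label(self, i: int) -> str:
        return self.labels[i]

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class ActivitySeries:
    """Binary activity of one hyperlink: the sorted steps at which it fires."""

    hyperlink: Hyperlink
    times: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(a >= b for a, b in zip(self.times, self.times[1:])):
            raise ValueError("activation times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class TemporalHypergraph:
    """The full record: node table + timestamped hyperevents on ``[0, T)``.

    ``dt`` is the duration of one step in native units (``dt_unit``, seconds
    for contact data, days for collaboration data); it only matters when
    curves are reported on native time axes.
    """

    nodes: NodeTable
    events: tuple[Event, ...]
    T: int
    dt: float = 1.0
    dt_unit: str = "s"
    contact_type: str = ""

    def __post_init__(self) -> None:
        self.events = tuple(self.events)
        n = len(self.nodes)
        seen: set[Event] = set()
        for ev in self.events:
            if ev in seen:
                raise ValueError(f"duplicate event {ev}")
            seen.add(ev)
            if not 0 <= ev.t < self.T:
                raise ValueError(f"event time {ev.t} outside [0, {self.T})")
            if ev.hyperlink[0] < 0 or ev.hyperlink[-1] >= n:
                raise ValueError(f"event references unknown node: {ev}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def orders(self) -> tuple[int, ...]:
        return tuple(sorted({ev.order for ev in self.events}))

    def events_of_order(self, d: int) -> tuple[Event, ...]:
        return tuple(ev for ev in self.events if ev.order == d)

    def with_events(self, events: Iterable[Event]) -> "TemporalHypergraph":
        """Copy with a new event set (same nodes, horizon and metadata)."""
        return replace(self, events=tuple(events))


@dataclass(frozen=True)
class AggregatedPairwiseGraph:
    """Unweighted pairwise aggregated network ``G``.

    An edge {u, v} is present iff u and v co-occur in at least one event of
    any order (each event's node set is a clique in ``G``).
    """

    n: int
    edges: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise ValueError("self-loop in aggregated graph")
            if not u < v:
                raise ValueError("edges must be stored as (min, max)")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class AggregatedHypergraph:
    """Weighted aggregated hypergraph ``H``: hyperlink -> activation count."""

    weights: Mapping[Hyperlink, int]

    @property
    def hyperlinks(self) -> tuple[Hyperlink, ...]:
        return tuple(self.weights)

    def of_order(self, d: int) -> tuple[Hyperlink, ...]:
        return tuple(h for h in self.weights if len(h) == d)

    def weight(self, h: Hyperlink) -> int:
        return self.weights[h]

    def __contains__(self, h: Hyperlink) -> bool:
        return h in self.weights

    def __len__(self) -> int:
        return len(self.weights)


class OrderCensus(NamedTuple):
    n_hyperlinks: int
    n_events: int


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _infer_step(raw_times: Sequence[int]) -> int:
    """Step duration as the gcd of distinct inter-record time differences."""
    uniq = sorted(set(raw_times))
    if len(uniq) < 2:
        return 1
    g = 0
    for a, b in zip(uniq, uniq[1:]):
        g = math.gcd(g, b - a)
    return g or 1


def _rescale(raw: list[tuple[int, tuple[str, ...]]], step: int | None,
             ) -> tuple[list[tuple[int, tuple[str, ...]]], int]:
    """Shift raw timestamps to start at 0 and divide by the step length."""
    times = [t for t, _ in raw]
    if step is None:
        step = _infer_step(times)
    t0 = min(times)
    return [((t - t0) // step, labs) for t, labs in raw], step


def read_contact_list(path: str | Path, dialect: str = "tij",
                      dt: int | None = None, dt_unit: str = "s",
                      contact_type: str = "physical") -> TemporalHypergraph:
    """Read a SocioPatterns-style ``tij`` pairwise contact list.

    Each non-comment line is ``timestamp node node`` (whitespace separated;
    extra trailing columns ignored).  Timestamps are divided by ``dt`` (the
    gcd of inter-record differences when not given) and shifted so the first
    contact is at step 0.  Duplicate records collapse to one event; self
    contacts (``i == j``) are rejected with a logged report.
    """
    if dialect != "tij":
        raise ValueError(f"unknown dialect {dialect!r}")
    raw: list[tuple[int, tuple[str, ...]]] = []
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected 't i j', got {line!r}")
            try:
                t = int(parts[0])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad timestamp {parts[0]!r}") from exc
            i, j = parts[1], parts[2]
            if i == j:
                n_self += 1
                logger.warning("%s:%d: self-contact %r rejected", path, lineno, line)
                continue
            raw.append((t, (i, j)))
    if n_self:
        logger.info("rejected %d self-contact lines", n_self)
    if not raw:
        return TemporalHypergraph(NodeTable(()), (), T=0, dt=float(dt or 1),
                                  dt_unit=dt_unit, contact_type=contact_type)
    scaled, step = _rescale(raw, dt)
    nodes = NodeTable.from_labels(itertools.chain.from_iterable(labs for _, labs in scaled))
    idx = nodes.index
    events = {Event(hyperlink(idx[l] for l in labs), t) for t, labs in scaled}
    n_dup = len(scaled) - len(events)
    if n_dup:
        logger.info("collapsed %d duplicate contact records", n_dup)
    T = max(ev.t for ev in events) + 1
    return TemporalHypergraph(nodes, tuple(sorted(events, key=_event_key)),
                              T=T, dt=float(step), dt_unit=dt_unit,
                              contact_type=contact_type)


_HEADER_RE = re.compile(
    r"#\s*T=(?P<T>\d+)\s+dt=(?P<dt>[0-9.eE+-]+)\s+unit=(?P<unit>\S+)"
    r"(?:\s+contact_type=(?P<ct>\S*))?")


def read_hyperevent_list(path: str | Path) -> TemporalHypergraph:
    """Read the native hyperevent TSV: ``t<TAB>label1,label2,...`` per line.

    A header comment ``# T=... dt=... unit=...`` (written by
    :func:`write_hyperevent_list`) pins the horizon and step length; without
    it, timestamps get the same gcd rescaling as contact lists.
    """
    raw: list[tuple[int, tuple[str, ...]]] = []
    header = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                m = _HEADER_RE.match(line.lstrip())
                if m:
                    header = m
                continue
            try:
                tpart, labpart = line.split("\t", 1)
                t = int(tpart)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: expected 't<TAB>labels'") from exc
            labels = tuple(labpart.split(","))
            if len(labels) < 2:
                raise ParseError(f"{path}:{lineno}: event needs >= 2 nodes")
            if len(set(labels)) != len(labels):
                raise ParseError(f"{path}:{lineno}: repeated label in event")
            raw.append((t, labels))
    dt, dt_unit, contact_type = 1.0, "s", ""
    if header is not None:
        dt = float(header["dt"])
        dt_unit = header["unit"]
        contact_type = header["ct"] or ""
    if not raw:
        T = int(header["T"]) if header is not None else 0
        return TemporalHypergraph(NodeTable(()), (), T=T, dt=dt,
                                  dt_unit=dt_unit, contact_type=contact_type)
    if header is None:
        raw, step = _rescale(raw, None)
        dt = float(step)
    nodes = NodeTable.from_labels(itertools.chain.from_iterable(labs for _, labs in raw))
    idx = nodes.index
    events = {Event(hyperlink(idx[l] for l in labs), t) for t, labs in raw}
    tmax = max(ev.t for ev in events)
    T = int(header["T"]) if header is not None else tmax + 1
    if T <= tmax:
        raise ParseError(f"{path}: header T={T} smaller than max event step {tmax}")
    return TemporalHypergraph(nodes, tuple(sorted(events, key=_event_key)),
                              T=T, dt=dt, dt_unit=dt_unit, contact_type=contact_type)


def _event_key(ev: Event) -> tuple:
    return (ev.t, ev.hyperlink)


def write_hyperevent_list(net: TemporalHypergraph, path: str | Path) -> None:
    """Write the hyperevent TSV; ordering is (t, node-label tuple), bit-stable."""
    rows = sorted(
        (ev.t, tuple(sorted(net.nodes.label(v) for v in ev.hyperlink)))
        for ev in net.events
    )
    with open(path, "w") as fh:
        fh.write("# hyperevent list\n")
        fh.write(f"# T={net.T} dt={net.dt:g} unit={net.dt_unit} "
                 f"contact_type={net.contact_type}\n")
        for t, labels in rows:
            fh.write(f"{t}\t{','.join(labels)}\n")


# ---------------------------------------------------------------------------
# aggregations
# ---------------------------------------------------------------------------

def aggregate_pairwise(net: TemporalHypergraph) -> AggregatedPairwiseGraph:
    """Project every event's node set to a clique; union over all events."""
    edges: set[tuple[int, int]] = set()
    for ev in net.events:
        edges.update(itertools.combinations(ev.hyperlink, 2))
    return AggregatedPairwiseGraph(n=net.n_nodes, edges=frozenset(edges))


def aggregate_higher_order(net: TemporalHypergraph) -> AggregatedHypergraph:
    """Weighted aggregation: one entry per distinct hyperlink, weight = count."""
    weights = Counter(ev.hyperlink for ev in net.events)
    return AggregatedHypergraph(weights=dict(weights))


def activity_series(net: TemporalHypergraph, h: Hyperlink) -> ActivitySeries:
    """Sorted activation times of exactly hyperlink ``h`` (empty if absent)."""
    times = sorted(ev.t for ev in net.events if ev.hyperlink == h)
    return ActivitySeries(hyperlink=tuple(h), times=tuple(times))


def order_census(net: TemporalHypergraph) -> dict[int, OrderCensus]:
    """Per order: (number of distinct hyperlinks, number of events)."""
    ev_count: Counter[int] = Counter(ev.order for ev in net.events)
    link_count: Counter[int] = Counter(
        len(h) for h in {ev.hyperlink for ev in net.events})
    return {d: OrderCensus(link_count[d], ev_count[d]) for d in sorted(ev_count)}


def descriptives(net: TemporalHypergraph) -> dict[str, object]:
    """Dataset-summary row: |N|, |L|, |E|, T, dt and contact type."""
    n_links = len({ev.hyperlink for ev in net.events})
    return {
        "n_nodes": net.n_nodes,
        "n_hyperlinks": n_links,
        "n_events": net.n_events,
        "T": net.T,
        "dt": net.dt,
        "dt_unit": net.dt_unit,
        "contact_type": net.contact_type,
    }
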