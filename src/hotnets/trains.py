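"""Egonetwork activity series and event-train statistics.

The egonetwork of an order-d hyperlink h is h itself plus every hyperlink of
strictly lower order sharing at least one node with h in the aggregated
hypergraph.  Its aggregated activity series sums the member hyperlinks'
binary activity per step.  A *train* is a maximal run of active steps whose
consecutive gaps are at most a reference interval (inclusive); its size is
the number of events it contains (summed activity over the span), and it is
center-active when the center hyperlink fires inside the span.  Pooling the
center-active trains of the egonetworks of every order-d hyperlink gives the
train-size distribution used to compare a network against its randomized
references.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

from .core import (
    AggregatedHypergraph,
    Hyperlink,
    TemporalHypergraph,
    aggregate_higher_order,
)

__all__ = [
    "Egonetwork",
    "Train",
    "TrainSizeDistribution",
    "build_egonetwork",
    "ego_activity",
    "detect_trains",
    "train_size_distribution",
    "native_to_steps",
]

#: Aggregated activity: time step -> number of simultaneous member activations.
CountSeries = dict[int, int]


@dataclass(frozen=True)
class Egonetwork:
    center: Hyperlink
    members: tuple[Hyperlink, ...]


@dataclass(frozen=True)
class Train:
    start: int
    end: int
    size: int
    center_active: bool


@dataclass(frozen=True)
class TrainSizeDistribution:
    delta_t: int
    d: int
    probabilities: dict[int, float]   # Pr[size = s] over center-active trains
    average_size: float
    n_trains: int


def build_egonetwork(H: AggregatedHypergraph, center: Hyperlink) -> Egonetwork:
    """Center plus all strictly-lower-order hyperlinks sharing >= 1 node."""
    if center not in H:
        raise KeyError(f"hyperlink {center} not in the aggregated hypergraph")
    d = len(center)
    cset = set(center)
    members = [center]
    members += [h for h in H.hyperlinks
                if len(h) < d and not cset.isdisjoint(h)]
    return Egonetwork(center=center, members=tuple(members))


def ego_activity(net: TemporalHypergraph, ego: Egonetwork) -> CountSeries:
    """Pointwise sum of the member hyperlinks' binary activity series."""
    members = set(ego.members)
    series: CountSeries = defaultdict(int)
    for ev in net.events:
        if ev.hyperlink in members:
            series[ev.t] += 1
    return dict(series)


def detect_trains(
    series: Mapping[int, int], delta_t: int,
    center_times: Iterable[int] = (),
) -> list[Train]:
    """Partition the active steps into trains at reference interval delta_t.

    Consecutive active steps with gap <= delta_t (inclusive boundary) belong
    to the same train; a larger gap starts a new one.  A train's size sums
    the activity over its span; it is center-active when any center
    activation falls inside [start, end].
    """
    if delta_t < 1:
        raise ValueError("delta_t must be >= 1")
    steps = sorted(series)
    centers = sorted(center_times)
    trains: list[Train] = []

    def close(run: list[int]) -> None:
        start, end = run[0], run[-1]
        size = sum(series[t] for t in run)
        active = any(start <= t <= end for t in centers)
        trains.append(Train(start=start, end=end, size=size, center_active=active))

    run: list[int] = []
    for t in steps:
        if run and t - run[-1] > delta_t:
            close(run)
            run = []
        run.append(t)
    if run:
        close(run)
    return trains


def train_size_distribution(
    net: TemporalHypergraph, d: int, delta_t: int,
    H: AggregatedHypergraph | None = None,
) -> TrainSizeDistribution:
    """Pooled center-active train sizes over all order-d egonetworks.

    For every order-d hyperlink, trains are detected on its egonetwork's
    aggregated activity series; only trains containing at least one center
    activation are kept.  Trains from overlapping egonetworks are pooled
    without deduplication.  An empty pool yields an empty distribution with
    nan mean.
    """
    if H is None:
        H = aggregate_higher_order(net)
    centers = H.of_order(d)
    if not centers:
        raise ValueError(f"no order-{d} hyperlinks")
    # per-hyperlink activity, plus node -> lower-order hyperlink index
    series: dict[Hyperlink, list[int]] = defaultdict(list)
    for ev in net.events:
        series[ev.hyperlink].append(ev.t)
    by_node: dict[int, list[Hyperlink]] = defaultdict(list)
    for h in H.hyperlinks:
        if len(h) < d:
            for v in h:
                by_node[v].append(h)
    sizes: Counter[int] = Counter()
    n_trains = 0
    for center in centers:
        members = {center}
        for v in center:
            members.update(h for h in by_node[v])
        agg: CountSeries = defaultdict(int)
        for h in members:
            for t in series[h]:
                agg[t] += 1
        for train in detect_trains(agg, delta_t, series[center]):
            if train.center_active:
                sizes[train.size] += 1
                n_trains += 1
    if n_trains == 0:
        return TrainSizeDistribution(delta_t, d, {}, math.nan, 0)
    probs = {s: c / n_trains for s, c in sorted(sizes.items())}
    avg = sum(s * c for s, c in sizes.items()) / n_trains
    return TrainSizeDistribution(delta_t, d, probs, avg, n_trains)


def native_to_steps(net: TemporalHypergraph, delta_native: float) -> int:
    """Convert a reference interval in native units to whole steps (>= 1)."""
    return max(1, round(delta_native / net.dt))
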