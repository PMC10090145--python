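"""Order-targeted randomized reference models.

Each model randomizes events of a single order d, leaving every other order
untouched, and preserves the unweighted aggregated hypergraph H (hence also
the pairwise aggregated graph G):

* ``H1``: reshuffles the timestamps of order-d events across those events.
  Hyperlink locations and per-hyperlink activation counts are preserved;
  per-hyperlink temporal structure (burstiness) is destroyed.
* ``H2``: permutes the whole activity time series among order-d hyperlinks
  uniformly.  The multiset of order-d series (hence the order-d inter-event
  time distribution) is preserved, but series are detached from their
  topological location; per-hyperlink weights redistribute.
* ``H3``: as ``H2`` but only among hyperlinks with equal total activations,
  so every per-hyperlink weight is preserved exactly.

The swap-based models are realized as a single uniform permutation, the
stationary distribution of iterated random transpositions, which makes a
realization reproducible from one seed.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .core import Event, Hyperlink, TemporalHypergraph

__all__ = [
    "RandomizationSpec",
    "randomize_H1",
    "randomize_H2",
    "randomize_H3",
    "randomize",
    "realizations",
]


@dataclass(frozen=True)
class RandomizationSpec:
    model: str                 # "H1" | "H2" | "H3"
    d: int
    seed: int
    realizations: int = 10

    def __post_init__(self) -> None:
        if self.model not in ("H1", "H2", "H3"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.d < 2:
            raise ValueError("order must be >= 2")
        if self.realizations < 1:
            raise ValueError("need >= 1 realization")


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _split(net: TemporalHypergraph, d: int) -> tuple[list[Event], list[Event]]:
    target = [ev for ev in net.events if ev.order == d]
    rest = [ev for ev in net.events if ev.order != d]
    return target, rest


def randomize_H1(
    net: TemporalHypergraph, d: int,
    seed: int | np.random.Generator | None = None,
) -> TemporalHypergraph:
    """Timestamp reshuffle of order-d events.

    The multiset of order-d timestamps is permuted across the order-d
    events; duplicate (hyperlink, t) assignments are repaired by random
    transpositions.  If no collision-free assignment is found the input is
    returned unchanged with a warning.
    """
    rng = _rng(seed)
    target, rest = _split(net, d)
    if not target:
        raise ValueError(f"no order-{d} events to randomize")
    hs = [ev.hyperlink for ev in target]
    ts = np.array([ev.t for ev in target], dtype=np.int64)
    ts = ts[rng.permutation(len(ts))]
    max_tries = 100 * len(ts) + 100
    for _ in range(max_tries):
        slots: dict[tuple[Hyperlink, int], int] = {}
        dup = -1
        for i, (h, t) in enumerate(zip(hs, ts)):
            key = (h, int(t))
            if key in slots:
                dup = i
                break
            slots[key] = i
        if dup < 0:
            break
        j = int(rng.integers(len(ts)))
        ts[dup], ts[j] = ts[j], ts[dup]
    else:
        warnings.warn("H1: could not resolve timestamp collisions; "
                      "returning the input unchanged")
        return net.with_events(net.events)
    events = rest + [Event(h, int(t)) for h, t in zip(hs, ts)]
    return net.with_events(sorted(events))


def _series_permutation(
    net: TemporalHypergraph, d: int, perm_within_equal_weight: bool,
    rng: np.random.Generator,
) -> TemporalHypergraph:
    target, rest = _split(net, d)
    if not target:
        raise ValueError(f"no order-{d} events to randomize")
    series: dict[Hyperlink, list[int]] = defaultdict(list)
    for ev in target:
        series[ev.hyperlink].append(ev.t)
    hs = sorted(series)
    if perm_within_equal_weight:
        groups: dict[int, list[int]] = defaultdict(list)
        for i, h in enumerate(hs):
            groups[len(series[h])].append(i)
        perm = np.arange(len(hs))
        for idxs in groups.values():
            idxs_arr = np.array(idxs)
            perm[idxs_arr] = idxs_arr[rng.permutation(len(idxs_arr))]
    else:
        perm = rng.permutation(len(hs))
    events = list(rest)
    for i, h in enumerate(hs):
        events.extend(Event(h, t) for t in series[hs[int(perm[i])]])
    return net.with_events(sorted(events))


def randomize_H2(
    net: TemporalHypergraph, d: int,
    seed: int | np.random.Generator | None = None,
) -> TemporalHypergraph:
    """Uniform permutation of activity series among order-d hyperlinks."""
    return _series_permutation(net, d, False, _rng(seed))


def randomize_H3(
    net: TemporalHypergraph, d: int,
    seed: int | np.random.Generator | None = None,
) -> TemporalHypergraph:
    """Activity-series permutation restricted to equal-activation hyperlinks."""
    return _series_permutation(net, d, True, _rng(seed))


_MODELS = {"H1": randomize_H1, "H2": randomize_H2, "H3": randomize_H3}


def randomize(
    net: TemporalHypergraph, model: str, d: int,
    seed: int | np.random.Generator | None = None,
) -> TemporalHypergraph:
    """Dispatch to one of the three models by name."""
    try:
        fn = _MODELS[model]
    except KeyError:
        raise ValueError(f"unknown model {model!r}") from None
    return fn(net, d, seed)


def realizations(
    net: TemporalHypergraph, spec: RandomizationSpec,
) -> Iterator[TemporalHypergraph]:
    """Independent randomized realizations from one spec (seeded streams)."""
    streams = np.random.SeedSequence(spec.seed).spawn(spec.realizations)
    for ss in streams:
        yield randomize(net, spec.model, spec.d, np.random.default_rng(ss))
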