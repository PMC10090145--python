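"""Seeded generators for higher-order temporal networks with known structure.

Three generators cover the regimes the characterization methods are meant to
tell apart:

* :func:`generate_uncorrelated` — hyperlinks drawn on a ring lattice (or
  uniformly), activation times i.i.d. uniform (or bursty, with heavy-tailed
  inter-event times): the world the randomized references describe.
* :func:`generate_coupled` — additionally, each higher-order "anchor" event
  spawns, with probability ``p_c``, lower-order events on hyperlinks at
  topological distance <= 1 (sharing a node), after a short geometric lag:
  a positive control with planted temporal-topological correlation, with
  ground-truth spawn records for oracle tests.
* :func:`generate_contact_sequence` — an order-2-only contact stream with
  planted cliques and near-cliques (one edge missing) at known steps, with a
  manifest, as a fixture for clique promotion and missing-link completion.

The ring-lattice locality gives the aggregated graph a nontrivial hop-count
structure (diameter ~ n / neighbourhood width), which the event-distance
statistics need; the uniform mode is a degenerate control.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .core import (
    Event,
    Hyperlink,
    NodeTable,
    TemporalHypergraph,
    hyperlink,
)

__all__ = [
    "SynthConfig",
    "SpawnRecord",
    "PlantedStructure",
    "generate_uncorrelated",
    "generate_coupled",
    "generate_contact_sequence",
]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic generators.

    Defaults give a desk-scale network (300 nodes, 5000 steps) with 600
    order-2 and 200 order-3 hyperlinks on a ring lattice of radius 5, a mean
    of 3 activations per hyperlink, and — when coupling is on — probability
    0.9 that an order-3 anchor event spawns neighbouring order-2 events
    (about three of them) after a geometric lag of mean 8 steps.
    """

    n: int = 300
    T: int = 5000
    links_per_order: dict[int, int] = field(
        default_factory=lambda: {2: 600, 3: 200})
    mean_activations: float = 3.0
    bursty: bool = False
    zeta_exponent: float = 2.2
    p_c: float = 0.0
    spawn_mean_extra: float = 2.0
    lag_scale: float = 8.0
    locality: str = "ring"          # "ring" | "uniform"
    radius: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3 or self.T < 2:
            raise ValueError("need n >= 3 and T >= 2")
        if not all(c > 0 for c in self.links_per_order.values()):
            raise ValueError("hyperlink counts must be positive")
        if not 0.0 <= self.p_c <= 1.0:
            raise ValueError("p_c must lie in [0, 1]")
        if self.locality not in ("ring", "uniform"):
            raise ValueError(f"unknown locality {self.locality!r}")


class SpawnRecord(NamedTuple):
    """Ground truth for one planted coupling: anchor event -> spawned event."""

    anchor: Hyperlink
    anchor_t: int
    spawned: Hyperlink
    spawned_t: int


class PlantedStructure(NamedTuple):
    """Ground truth for one planted contact structure."""

    t: int
    kind: str                       # "clique" | "near_clique"
    nodes: tuple[int, ...]
    missing_edge: tuple[int, int] | None


def _node_table(n: int) -> NodeTable:
    return NodeTable(tuple(f"n{i}" for i in range(n)))


def _draw_hyperlinks(cfg: SynthConfig, rng: np.random.Generator) -> dict[int, list[Hyperlink]]:
    links: dict[int, list[Hyperlink]] = {}
    for d, count in sorted(cfg.links_per_order.items()):
        if math.comb(cfg.n, d) < count:
            raise ValueError(
                f"cannot draw {count} distinct order-{d} hyperlinks from {cfg.n} nodes")
        chosen: set[Hyperlink] = set()
        tries = 0
        while len(chosen) < count:
            tries += 1
            if tries > 200 * count:
                raise ValueError(
                    f"could not draw {count} distinct order-{d} hyperlinks "
                    f"(locality={cfg.locality}, radius={cfg.radius})")
            if cfg.locality == "uniform":
                nodes = rng.choice(cfg.n, size=d, replace=False)
            else:
                center = int(rng.integers(cfg.n))
                window = [(center + off) % cfg.n
                          for off in range(-cfg.radius, cfg.radius + 1)
                          if off != 0]
                others = rng.choice(len(window), size=d - 1, replace=False)
                nodes = [center] + [window[i] for i in others]
            chosen.add(hyperlink(int(v) for v in nodes))
        links[d] = sorted(chosen)
    return links


def _uniform_times(cfg: SynthConfig, rng: np.random.Generator, n_act: int) -> list[int]:
    return sorted(int(t) for t in rng.choice(cfg.T, size=n_act, replace=False))


def _bursty_times(cfg: SynthConfig, rng: np.random.Generator, n_act: int) -> list[int]:
    """Heavy-tailed (truncated zeta) inter-event times from a random start."""
    start = int(rng.integers(cfg.T))
    times = [start]
    while len(times) < n_act:
        gap = int(rng.zipf(cfg.zeta_exponent))
        gap = min(gap, cfg.T // 2)
        nxt = times[-1] + gap
        if nxt >= cfg.T:
            break
        times.append(nxt)
    return times


def _activate(cfg: SynthConfig, rng: np.random.Generator,
              links: dict[int, list[Hyperlink]]) -> set[Event]:
    events: set[Event] = set()
    for d in sorted(links):
        for h in links[d]:
            n_act = max(1, int(rng.poisson(cfg.mean_activations)))
            n_act = min(n_act, cfg.T)
            draw = _bursty_times if cfg.bursty else _uniform_times
            for t in draw(cfg, rng, n_act):
                events.add(Event(h, t))
    return events


def generate_uncorrelated(cfg: SynthConfig) -> TemporalHypergraph:
    """Negative control: no coupling between orders is planted."""
    rng = np.random.default_rng(cfg.seed)
    links = _draw_hyperlinks(cfg, rng)
    events = _activate(cfg, rng, links)
    return TemporalHypergraph(_node_table(cfg.n), tuple(sorted(events)),
                              T=cfg.T, dt=1.0, dt_unit="s",
                              contact_type="synthetic")


def generate_coupled(
    cfg: SynthConfig,
) -> tuple[TemporalHypergraph, list[SpawnRecord]]:
    """Positive control with planted temporal-topological correlation.

    Each event of the highest configured order ("anchor") spawns, with
    probability ``p_c``, a batch of order-2 events (1 + Poisson of mean
    ``spawn_mean_extra``) on hyperlinks sharing at least one node with the
    anchor, each delayed by an independent geometric lag of mean
    ``lag_scale`` steps.  Ground-truth spawn records are returned for
    oracle tests.  With ``p_c = 0`` this reduces to the uncorrelated
    generator distributionally.
    """
    rng = np.random.default_rng(cfg.seed)
    links = _draw_hyperlinks(cfg, rng)
    events = _activate(cfg, rng, links)
    spawns: list[SpawnRecord] = []
    if cfg.p_c > 0 and len(links) >= 2:
        anchor_order = max(links)
        lower = links.get(2, [])
        by_node: dict[int, list[Hyperlink]] = {}
        for h in lower:
            for v in h:
                by_node.setdefault(v, []).append(h)
        anchors = sorted(ev for ev in events if ev.order == anchor_order)
        for anchor in anchors:
            if rng.random() >= cfg.p_c:
                continue
            neigh = sorted({h for v in anchor.hyperlink
                            for h in by_node.get(v, ())})
            if not neigh:
                continue
            n_spawn = 1 + int(rng.poisson(cfg.spawn_mean_extra))
            for _ in range(n_spawn):
                h2 = neigh[int(rng.integers(len(neigh)))]
                lag = int(rng.geometric(1.0 / cfg.lag_scale))
                t2 = anchor.t + lag
                if t2 >= cfg.T:
                    continue
                ev2 = Event(h2, t2)
                if ev2 in events:
                    continue
                events.add(ev2)
                spawns.append(SpawnRecord(anchor.hyperlink, anchor.t, h2, t2))
    net = TemporalHypergraph(_node_table(cfg.n), tuple(sorted(events)),
                             T=cfg.T, dt=1.0, dt_unit="s",
                             contact_type="synthetic")
    return net, spawns


def generate_contact_sequence(
    cfg: SynthConfig, structures_per_step: int = 3, n_steps: int = 40,
) -> tuple[TemporalHypergraph, list[PlantedStructure]]:
    """Order-2 contact stream with planted cliques and near-cliques.

    At each of ``n_steps`` time steps (spread over [0, T)), a few
    node-disjoint structures are planted: full cliques of size 2-5 or
    near-cliques (a clique of size 4-5 with exactly one edge removed).
    Only the structures' pairwise contacts are emitted, along with a
    manifest for oracle tests: promotion must recover each planted clique
    as one event of its size, and completion + promotion must recover each
    near-clique as one event of its full size.
    """
    rng = np.random.default_rng(cfg.seed)
    steps = sorted(int(t) for t in rng.choice(cfg.T, size=min(n_steps, cfg.T),
                                              replace=False))
    kinds = ["clique", "near_clique"]
    events: set[Event] = set()
    manifest: list[PlantedStructure] = []
    for t in steps:
        pool = list(rng.permutation(cfg.n))
        for _ in range(structures_per_step):
            kind = kinds[int(rng.integers(2))]
            size = int(rng.integers(2, 6)) if kind == "clique" else int(rng.integers(4, 6))
            if len(pool) < size:
                break
            nodes = tuple(sorted(int(pool.pop()) for _ in range(size)))
            pairs = list(itertools.combinations(nodes, 2))
            missing = None
            if kind == "near_clique":
                missing = pairs.pop(int(rng.integers(len(pairs))))
            for u, v in pairs:
                events.add(Event(hyperlink((u, v)), t))
            manifest.append(PlantedStructure(t, kind, nodes, missing))
    net = TemporalHypergraph(_node_table(cfg.n), tuple(sorted(events)),
                             T=cfg.T, dt=1.0, dt_unit="s",
                             contact_type="synthetic")
    return net, manifest
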