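"""Event-to-event topological distance and conditional distance-delay curves.

The topological distance between two events is 0 when they activate the same
hyperlink, and otherwise one plus the minimal hop count, on the unweighted
pairwise aggregated graph G, between a component node of one event and a
component node of the other.  The temporal distance is the absolute delay in
steps.

The headline statistic is the conditional mean topological distance between
event pairs whose delay is below a threshold dt, swept over a grid of
thresholds and normalized by the unconditional mean over the same pair
population:

* cross-order (mu_d): pairs of one order-d event and one event of any other
  order;
* same-order (nu_d): unordered pairs of distinct order-d events.

An increasing normalized curve means events close in time are also close in
topology; the strength is summarized by a least-squares slope of the curve
against log10 of the delay threshold, fitted over the increasing part
(from the curve's argmin to the end).
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import (
    AggregatedPairwiseGraph,
    Event,
    Hyperlink,
    TemporalHypergraph,
    aggregate_pairwise,
)

__all__ = [
    "DistanceCurve",
    "SlopeFit",
    "node_distances",
    "event_distance",
    "temporal_distance",
    "distance_curve",
    "fit_increasing_slope",
]

_UNREACHABLE = np.iinfo(np.int32).max


def _adjacency(G: AggregatedPairwiseGraph) -> list[list[int]]:
    adj: list[list[int]] = [[] for _ in range(G.n)]
    for u, v in G.edges:
        adj[u].append(v)
        adj[v].append(u)
    return adj


def _bfs(adj: list[list[int]], sources: Iterable[int]) -> np.ndarray:
    """Multi-source BFS hop counts; unreachable nodes get a large sentinel."""
    dist = np.full(len(adj), _UNREACHABLE, dtype=np.int64)
    q: deque[int] = deque()
    for s in sources:
        dist[s] = 0
        q.append(s)
    while q:
        u = q.popleft()
        du = dist[u] + 1
        for v in adj[u]:
            if dist[v] == _UNREACHABLE:
                dist[v] = du
                q.append(v)
    return dist


def node_distances(
    G: AggregatedPairwiseGraph, sources: Iterable[int]
) -> dict[tuple[int, int], float]:
    """BFS hop counts from each source to every node (inf if unreachable)."""
    adj = _adjacency(G)
    out: dict[tuple[int, int], float] = {}
    for s in sources:
        dist = _bfs(adj, [s])
        for v in range(G.n):
            out[(s, v)] = math.inf if dist[v] == _UNREACHABLE else float(dist[v])
    return out


def event_distance(e1: Event, e2: Event, G: AggregatedPairwiseGraph) -> float:
    """Topological distance between two events on G.

    0 iff the two events activate the same hyperlink; otherwise
    ``1 + min over node pairs of the hop count``; ``inf`` when every
    component-node pair is unreachable (cannot occur after restriction to
    the largest connected component).
    """
    if e1.hyperlink == e2.hyperlink:
        return 0.0
    adj = _adjacency(G)
    dist = _bfs(adj, e1.hyperlink)
    best = min(dist[v] for v in e2.hyperlink)
    return math.inf if best == _UNREACHABLE else float(best + 1)


def temporal_distance(e1: Event, e2: Event) -> int:
    """Absolute delay in steps between two events."""
    return abs(e1.t - e2.t)


@dataclass(frozen=True)
class DistanceCurve:
    """Conditional mean topological distance versus delay threshold."""

    kind: str                      # "cross_order" | "same_order"
    d: int
    grid: np.ndarray               # increasing delay thresholds (steps)
    pair_counts: np.ndarray        # pairs with delay < grid point
    mean_dist: np.ndarray          # conditional mean (nan where count 0)
    normalized: np.ndarray         # mean / unconditional mean
    unconditional_mean: float
    estimator: str                 # "exact" | "sampled(n=..., seed=...)"
    dt: float = 1.0                # step length in native units
    stderr: np.ndarray | None = None
    n_unreachable_pairs: int = 0


def default_grid(T: int, n_points: int = 50) -> np.ndarray:
    """Deduplicated log-spaced integer delay thresholds from 1 to T."""
    top = max(T, 2)
    return np.unique(np.round(np.geomspace(1, top, n_points)).astype(np.int64))


def _hyperlink_eta(
    G: AggregatedPairwiseGraph,
    rows: Sequence[Hyperlink],
    cols: Sequence[Hyperlink],
    same: bool,
) -> np.ndarray:
    """Matrix of event distances between hyperlinks (row x col).

    Entry is 0 on the diagonal when ``same`` (identical hyperlink), else
    1 + min hop count between the two node sets; inf when disconnected.
    """
    adj = _adjacency(G)
    eta = np.empty((len(rows), len(cols)))
    col_nodes = [np.fromiter(h, dtype=np.int64) for h in cols]
    for i, h in enumerate(rows):
        dist = _bfs(adj, h)
        for j, nodes in enumerate(col_nodes):
            m = dist[nodes].min()
            eta[i, j] = np.inf if m == _UNREACHABLE else m + 1.0
    if same:
        np.fill_diagonal(eta, 0.0)
    return eta


def distance_curve(
    net: TemporalHypergraph,
    d: int,
    kind: str = "cross_order",
    grid: Sequence[int] | None = None,
    estimator: str = "auto",
    sample_size: int = 1_000_000,
    seed: int | None = None,
    max_exact_pairs: int = 20_000_000,
    G: AggregatedPairwiseGraph | None = None,
) -> DistanceCurve:
    """Conditional distance-delay curve (cross-order mu_d or same-order nu_d).

    For each threshold in ``grid`` the curve holds the mean topological
    distance over the pair population with delay strictly below the
    threshold, the pair count, and the ratio to the unconditional mean
    (which the curve approaches as the threshold exceeds the maximal delay).
    Pairs are unordered and counted once; self-pairs are excluded;
    simultaneous pairs enter every threshold >= 1.  ``G`` defaults to the
    pairwise aggregation of the full network and should be held fixed when
    comparing against randomized references (they preserve it anyway).

    The exact estimator enumerates all pairs; the sampled one draws
    ``sample_size`` pairs uniformly (seed required) and reports standard
    errors.  ``estimator='auto'`` switches to sampling above
    ``max_exact_pairs`` pairs.
    """
    if kind not in ("cross_order", "same_order"):
        raise ValueError(f"unknown kind {kind!r}")
    if G is None:
        G = aggregate_pairwise(net)
    ev_d = [ev for ev in net.events if ev.order == d]
    if not ev_d:
        raise ValueError(f"no order-{d} events")
    same = kind == "same_order"
    if same:
        ev_o = ev_d
        n_pairs = len(ev_d) * (len(ev_d) - 1) // 2
    else:
        ev_o = [ev for ev in net.events if ev.order != d]
        if not ev_o:
            raise ValueError("no events of other orders")
        n_pairs = len(ev_d) * len(ev_o)
    if n_pairs == 0:
        raise ValueError("no event pairs to average over")
    if grid is None:
        grid_arr = default_grid(net.T)
    else:
        grid_arr = np.asarray(grid, dtype=np.int64)
        if grid_arr.ndim != 1 or len(grid_arr) == 0 or grid_arr[0] < 1 or np.any(
                np.diff(grid_arr) <= 0):
            raise ValueError("grid must be strictly increasing positive ints")

    hs_d = sorted({ev.hyperlink for ev in ev_d})
    hs_o = hs_d if same else sorted({ev.hyperlink for ev in ev_o})
    hidx_d = {h: i for i, h in enumerate(hs_d)}
    hidx_o = {h: i for i, h in enumerate(hs_o)}
    eta = _hyperlink_eta(G, hs_d, hs_o, same=same)

    t_a = np.fromiter((ev.t for ev in ev_d), dtype=np.int64)
    h_a = np.fromiter((hidx_d[ev.hyperlink] for ev in ev_d), dtype=np.int64)
    t_b = np.fromiter((ev.t for ev in ev_o), dtype=np.int64)
    h_b = np.fromiter((hidx_o[ev.hyperlink] for ev in ev_o), dtype=np.int64)

    if estimator == "auto":
        estimator = "exact" if n_pairs <= max_exact_pairs else "sampled"
    nbins = len(grid_arr) + 1
    cnt = np.zeros(nbins, dtype=np.int64)
    s1 = np.zeros(nbins)
    s2 = np.zeros(nbins)
    n_inf = 0

    def accumulate(td: np.ndarray, w: np.ndarray) -> int:
        finite = np.isfinite(w)
        td, w = td[finite], w[finite]
        p = np.searchsorted(grid_arr, td, side="right")
        np.add.at(cnt, p, 1)
        np.add.at(s1, p, w)
        np.add.at(s2, p, w * w)
        return int((~finite).sum())

    if estimator == "exact":
        chunk = max(1, int(4_000_000 // max(len(t_b), 1)))
        for i0 in range(0, len(t_a), chunk):
            i1 = min(i0 + chunk, len(t_a))
            td = np.abs(t_a[i0:i1, None] - t_b[None, :])
            w = eta[h_a[i0:i1, None], h_b[None, :]]
            if same:
                # unordered distinct pairs: keep global j > i only
                mask = np.arange(len(t_b))[None, :] > np.arange(i0, i1)[:, None]
                td, w = td[mask], w[mask]
            else:
                td, w = td.ravel(), w.ravel()
            n_inf += accumulate(td, w)
        est_label = "exact"
    elif estimator == "sampled":
        if seed is None:
            raise ValueError("sampled estimator requires a seed")
        rng = np.random.default_rng(seed)
        drawn = 0
        while drawn < sample_size:
            take = min(sample_size - drawn, 2_000_000)
            i = rng.integers(0, len(t_a), take)
            j = rng.integers(0, len(t_b), take)
            if same:
                keep = i != j
                i, j = i[keep], j[keep]
            td = np.abs(t_a[i] - t_b[j])
            n_inf += accumulate(td, eta[h_a[i], h_b[j]])
            drawn += len(i)
        est_label = f"sampled(n={sample_size}, seed={seed})"
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    cum_n = np.cumsum(cnt)[: len(grid_arr)]
    cum_s1 = np.cumsum(s1)[: len(grid_arr)]
    cum_s2 = np.cumsum(s2)[: len(grid_arr)]
    total_n = int(cnt.sum())
    if total_n == 0:
        raise ValueError("all pairs unreachable; run on a connected network")
    uncond = float(s1.sum() / total_n)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cum_n > 0, cum_s1 / np.maximum(cum_n, 1), np.nan)
        norm = mean / uncond
        var = cum_s2 / np.maximum(cum_n, 1) - mean**2
        stderr = np.sqrt(np.maximum(var, 0.0) / np.maximum(cum_n, 1))
    stderr = np.where(cum_n > 0, stderr, np.nan)
    return DistanceCurve(
        kind=kind,
        d=d,
        grid=grid_arr,
        pair_counts=cum_n,
        mean_dist=mean,
        normalized=norm,
        unconditional_mean=uncond,
        estimator=est_label,
        dt=net.dt,
        stderr=stderr if estimator != "exact" else None,
        n_unreachable_pairs=n_inf,
    )


@dataclass(frozen=True)
class SlopeFit:
    """Least-squares slope of a normalized curve vs log10(delay)."""

    m: float                      # slope per decade of delay (native units)
    intercept: float
    fit_range: tuple[int, int]    # first/last grid indices used
    r2: float
    whole_curve_fallback: bool = False


def fit_increasing_slope(curve: DistanceCurve) -> SlopeFit:
    """Fit the increasing part of a normalized distance-delay curve.

    The fit regresses the normalized value on log10(threshold * dt) over
    the window from the curve's argmin (ties broken toward the largest
    index) to the last defined point.  If fewer than 3 points remain after
    the argmin, the whole defined curve is fitted and the result is flagged.
    """
    defined = np.flatnonzero(np.isfinite(curve.normalized))
    if len(defined) < 3:
        raise ValueError("need >= 3 defined grid points to fit a slope")
    y_def = curve.normalized[defined]
    rev_argmin = len(y_def) - 1 - int(np.argmin(y_def[::-1]))
    sel = defined[rev_argmin:]
    fallback = False
    if len(sel) < 3:
        sel = defined
        fallback = True
    x = np.log10(curve.grid[sel] * curve.dt)
    y = curve.normalized[sel]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
    else:
        r2 = 1.0 if ss_res < 1e-12 else 0.0
    return SlopeFit(
        m=float(slope),
        intercept=float(intercept),
        fit_range=(int(sel[0]), int(sel[-1])),
        r2=r2,
        whole_curve_fallback=fallback,
    )
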