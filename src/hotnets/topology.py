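"""Cross-order degree/strength statistics and binned relation curves.

For a node v and order d, the d-degree ``k_d(v)`` counts the distinct
order-d hyperlinks containing v in the aggregated hypergraph, and the
d-strength ``s_d(v)`` counts the order-d events v participates in (the sum
of weights of its order-d hyperlinks).  Two exact identities hold:
``sum_v k_d(v) = d * |L_d|`` and ``sum_v s_d(v) = d * |E_d|``.

The relation curves mirror the standard presentation: each axis restricted
to nodes where both quantities are non-zero, normalized by its maximum, and
the x-axis split into 30 bins (logarithmic for cross-order comparisons,
linear for strength-vs-degree, where the y-axis is instead normalized by
omega_d, the mean activations per order-d hyperlink, so that the reference
diagonal is s_d = omega_d * k_d).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import AggregatedHypergraph, TemporalHypergraph, aggregate_higher_order

__all__ = [
    "DegreeStrengthTable",
    "BinnedCurve",
    "degree_strength",
    "omega",
    "cross_order_relation",
    "strength_vs_degree",
    "rank_correlation",
]


@dataclass(frozen=True)
class DegreeStrengthTable:
    """Per-node, per-order degree and strength arrays (length = n nodes)."""

    n_nodes: int
    k: dict[int, np.ndarray]
    s: dict[int, np.ndarray]

    @property
    def orders(self) -> tuple[int, ...]:
        return tuple(sorted(self.k))

    def value(self, d: int, which: str) -> np.ndarray:
        if which == "degree":
            return self.k[d]
        if which == "strength":
            return self.s[d]
        raise ValueError(f"which must be 'degree' or 'strength', got {which!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.orders:
            for v in range(self.n_nodes):
                rows.append((v, d, int(self.k[d][v]), int(self.s[d][v])))
        return pd.DataFrame(rows, columns=["node", "order", "k", "s"])


def degree_strength(
    net: TemporalHypergraph, H: AggregatedHypergraph | None = None,
) -> DegreeStrengthTable:
    """Tabulate k_d(v) and s_d(v) for every node and observed order."""
    if H is None:
        H = aggregate_higher_order(net)
    n = net.n_nodes
    orders = sorted({len(h) for h in H.hyperlinks})
    k = {d: np.zeros(n, dtype=np.int64) for d in orders}
    s = {d: np.zeros(n, dtype=np.int64) for d in orders}
    for h, w in H.weights.items():
        d = len(h)
        for v in h:
            k[d][v] += 1
            s[d][v] += w
    return DegreeStrengthTable(n_nodes=n, k=k, s=s)


def omega(net_or_H: TemporalHypergraph | AggregatedHypergraph, d: int) -> float:
    """Mean activations per order-d hyperlink: |E_d| / |L_d|."""
    H = (net_or_H if isinstance(net_or_H, AggregatedHypergraph)
         else aggregate_higher_order(net_or_H))
    links = H.of_order(d)
    if not links:
        raise ValueError(f"no order-{d} hyperlinks")
    return sum(H.weights[h] for h in links) / len(links)


@dataclass(frozen=True)
class BinnedCurve:
    """30-bin mean curve; empty bins carry nan means and count 0."""

    edges: np.ndarray       # 31 edges on the x-axis
    x: np.ndarray           # 30 bin centers (geometric / arithmetic)
    mean: np.ndarray        # 30 per-bin mean y (nan when empty)
    count: np.ndarray       # 30 occupancy counts
    scale: str              # "log30" | "linear30"


def _bin_means(x: np.ndarray, y: np.ndarray, edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # a point exactly on an interior edge joins the left bin
    idx = np.searchsorted(edges, x, side="left") - 1
    idx = np.clip(idx, 0, len(edges) - 2)
    count = np.bincount(idx, minlength=len(edges) - 1)
    ysum = np.bincount(idx, weights=y, minlength=len(edges) - 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, ysum / np.maximum(count, 1), np.nan)
    return mean, count


def cross_order_relation(
    table: DegreeStrengthTable, d: int, d_prime: int, which: str = "degree",
    n_bins: int = 30,
) -> BinnedCurve:
    """Binned d'-quantity versus d-quantity over doubly active nodes.

    Restricts to nodes where both quantities are non-zero, normalizes each
    axis by its maximum over that restricted set, and averages the y values
    in ``n_bins`` logarithmic x bins spanning [min positive x, 1].  The
    reference diagonal is y = x.
    """
    xv = table.value(d, which).astype(float)
    yv = table.value(d_prime, which).astype(float)
    mask = (xv > 0) & (yv > 0)
    if not mask.any():
        edges = np.geomspace(0.5, 1.0, n_bins + 1)
        nanrow = np.full(n_bins, np.nan)
        return BinnedCurve(edges, np.sqrt(edges[:-1] * edges[1:]), nanrow,
                           np.zeros(n_bins, dtype=np.int64), f"log{n_bins}")
    xn = xv[mask] / xv[mask].max()
    yn = yv[mask] / yv[mask].max()
    lo = xn.min()
    if lo >= 1.0:           # all nodes at the maximum: one occupied bin at (1,1)
        lo = 0.5
    edges = np.geomspace(lo, 1.0, n_bins + 1)
    mean, count = _bin_means(xn, yn, edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    return BinnedCurve(edges, centers, mean, count, f"log{n_bins}")


def strength_vs_degree(
    table: DegreeStrengthTable, net: TemporalHypergraph, d: int,
    n_bins: int = 30,
) -> BinnedCurve:
    """Binned s_d / omega_d versus k_d; the reference diagonal is y = x."""
    kd = table.k[d].astype(float)
    sd = table.s[d].astype(float)
    mask = kd > 0
    if not mask.any():
        raise ValueError(f"no nodes with order-{d} hyperlinks")
    w = omega(net, d)
    x = kd[mask]
    y = sd[mask] / w
    lo, hi = x.min(), x.max()
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, n_bins + 1)
    mean, count = _bin_means(x, y, edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return BinnedCurve(edges, centers, mean, count, f"linear{n_bins}")


def rank_correlation(
    table: DegreeStrengthTable, d: int, d_prime: int, which: str = "degree",
) -> float:
    """Spearman correlation of the d- and d'-quantities over doubly active nodes."""
    xv = table.value(d, which).astype(float)
    yv = table.value(d_prime, which).astype(float)
    mask = (xv > 0) & (yv > 0)
    if mask.sum() < 3:
        return float("nan")
    rho, _ = stats.spearmanr(xv[mask], yv[mask])
    return float(rho)
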