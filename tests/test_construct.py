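"""Clique promotion, missing-link completion and preprocessing."""

import itertools

import networkx as nx
import numpy as np
import pytest

import hotnets as hn
from conftest import make_net


def brute_force_maximal_cliques(edges):
    """Enumerate maximal cliques by checking every node subset."""
    nodes = sorted({v for e in edges for v in e})
    eset = {tuple(sorted(e)) for e in edges}

    def is_clique(sub):
        return all(tuple(sorted(p)) in eset
                   for p in itertools.combinations(sub, 2))

    cliques = [set(sub) for r in range(2, len(nodes) + 1)
               for sub in itertools.combinations(nodes, r) if is_clique(sub)]
    return {tuple(sorted(c)) for c in cliques
            if not any(c < other for other in cliques)}


def test_promotion_triangle_becomes_single_order3_event():
    net = make_net([((0, 1), 7), ((1, 2), 7), ((0, 2), 7)])
    prom = hn.promote_cliques(net)
    assert set(prom.events) == {hn.Event(hn.hyperlink((0, 1, 2)), 7)}


def test_promotion_isolated_contact_stays_order2():
    net = make_net([((0, 1), 3)])
    prom = hn.promote_cliques(net)
    assert set(prom.events) == {hn.Event(hn.hyperlink((0, 1)), 3)}


def test_promotion_mixed_step():
    # edges ab, bc, ac, cd at one step -> triangle event + pair event
    net = make_net([((0, 1), 0), ((1, 2), 0), ((0, 2), 0), ((2, 3), 0)])
    prom = hn.promote_cliques(net)
    assert set(prom.events) == {
        hn.Event(hn.hyperlink((0, 1, 2)), 0),
        hn.Event(hn.hyperlink((2, 3)), 0),
    }


def test_promotion_matches_exhaustive_clique_oracle(rng):
    for _ in range(20):
        n, t = 7, 0
        edges = [tuple(sorted(p)) for p in itertools.combinations(range(n), 2)
                 if rng.random() < 0.4]
        if not edges:
            continue
        net = make_net([(e, t) for e in edges], n_nodes=n, T=1)
        got = {ev.hyperlink for ev in hn.promote_cliques(net).events}
        assert got == brute_force_maximal_cliques(edges)


def test_promotion_antichain_and_contact_conservation(rng):
    for _ in range(10):
        steps = {}
        for t in range(4):
            edges = {tuple(sorted(rng.choice(8, size=2, replace=False)))
                     for _ in range(8)}
            steps[t] = {e for e in edges if e[0] != e[1]}
        events = [(e, t) for t, es in steps.items() for e in es]
        if not events:
            continue
        net = make_net([(e, t) for e, t in events], n_nodes=8, T=4)
        prom = hn.promote_cliques(net)
        for t, es in steps.items():
            evs = [ev.hyperlink for ev in prom.events if ev.t == t]
            # antichain: no event node set contains another
            for a, b in itertools.combinations(evs, 2):
                assert not set(a) <= set(b) and not set(b) <= set(a)
            # union of 2-subsets equals the contact edge set
            union = {p for h in evs for p in itertools.combinations(h, 2)}
            assert union == es


def test_promotion_requires_order2_only(mixed_net):
    with pytest.raises(ValueError):
        hn.promote_cliques(mixed_net)


# ---------------------------------------------------------------------------
# missing-link completion
# ---------------------------------------------------------------------------

def k_minus_edge(nodes, missing):
    pairs = [p for p in itertools.combinations(nodes, 2) if p != missing]
    return pairs


def brute_force_missing_links(edges):
    """All non-edges (u, v) completing some >= 4 subset to a full clique."""
    nodes = sorted({v for e in edges for v in e})
    eset = {tuple(sorted(e)) for e in edges}
    added = set()
    for r in range(4, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            missing = [p for p in itertools.combinations(sub, 2)
                       if tuple(sorted(p)) not in eset]
            if len(missing) == 1:
                added.add(missing[0])
    return added


def test_completion_k4_minus_edge_promotes_to_order4():
    net = make_net([(p, 2) for p in k_minus_edge((0, 1, 2, 3), (0, 1))])
    comp, n_added = hn.complete_missing_links(net)
    assert n_added == 1
    prom = hn.promote_cliques(comp)
    assert set(prom.events) == {hn.Event(hn.hyperlink((0, 1, 2, 3)), 2)}


def test_completion_ignores_triangles_with_missing_edge():
    net = make_net([((0, 1), 0), ((1, 2), 0)])  # path: triangle minus (0,2)
    comp, n_added = hn.complete_missing_links(net)
    assert n_added == 0
    assert set(comp.events) == set(net.events)


def test_completion_k5_minus_edge_adds_single_edge():
    net = make_net([(p, 0) for p in k_minus_edge((0, 1, 2, 3, 4), (1, 3))])
    comp, n_added = hn.complete_missing_links(net)
    assert n_added == 1
    added = set(comp.events) - set(net.events)
    assert added == {hn.Event(hn.hyperlink((1, 3)), 0)}


def test_completion_matches_exhaustive_subset_oracle(rng):
    for _ in range(15):
        edges = {tuple(sorted(rng.choice(7, size=2, replace=False)))
                 for _ in range(12)}
        edges = {e for e in edges if e[0] != e[1]}
        if not edges:
            continue
        net = make_net([(e, 0) for e in edges], n_nodes=7, T=1)
        comp, _ = hn.complete_missing_links(net)
        got = {ev.hyperlink for ev in comp.events} - {
            hn.hyperlink(e) for e in edges}
        assert got == {hn.hyperlink(e) for e in brute_force_missing_links(edges)}


def test_completion_never_shrinks_largest_promotable_event(rng):
    for _ in range(10):
        edges = {tuple(sorted(rng.choice(8, size=2, replace=False)))
                 for _ in range(14)}
        edges = {e for e in edges if e[0] != e[1]}
        if not edges:
            continue
        net = make_net([(e, 0) for e in edges], n_nodes=8, T=1)
        before = max(ev.order for ev in hn.promote_cliques(net).events)
        comp, _ = hn.complete_missing_links(net)
        after = max(ev.order for ev in hn.promote_cliques(comp).events)
        assert after >= before


# ---------------------------------------------------------------------------
# LCC restriction
# ---------------------------------------------------------------------------

def test_lcc_connected_network_unchanged(mixed_net):
    out, report = hn.restrict_to_lcc(mixed_net)
    assert set(out.events) == set(mixed_net.events)
    assert report.nodes_removed == 0


def test_lcc_keeps_largest_component():
    net = make_net([((0, 1), 0), ((1, 2), 1), ((3, 4), 2)])
    out, report = hn.restrict_to_lcc(net)
    assert report.nodes_removed == 2
    assert out.n_nodes == 3
    labels = {tuple(out.nodes.label(v) for v in ev.hyperlink) for ev in out.events}
    assert labels == {("0", "1"), ("1", "2")}


def test_lcc_tie_break_smallest_min_node_id():
    net = make_net([((2, 3), 0), ((0, 1), 0)])
    out, _ = hn.restrict_to_lcc(net)
    labels = {tuple(out.nodes.label(v) for v in ev.hyperlink) for ev in out.events}
    assert labels == {("0", "1")}


def test_lcc_empty_network():
    net = make_net([], n_nodes=0, T=0)
    out, _ = hn.restrict_to_lcc(net)
    assert out.n_events == 0


def test_lcc_agrees_with_networkx_components(rng):
    for _ in range(10):
        edges = {tuple(sorted(rng.choice(12, size=2, replace=False)))
                 for _ in range(8)}
        edges = {e for e in edges if e[0] != e[1]}
        if not edges:
            continue
        net = make_net([(e, i % 3) for i, e in enumerate(sorted(edges))],
                       n_nodes=12, T=3)
        g = hn.aggregate_pairwise(net).to_networkx()
        comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
        keep = comps[0]
        out, _ = hn.restrict_to_lcc(net)
        kept_labels = {net.nodes.label(v) for v in keep
                       if any(v in ev.hyperlink for ev in net.events)}
        # every surviving event lies inside the chosen component
        assert {out.nodes.label(v) for ev in out.events
                for v in ev.hyperlink} <= {net.nodes.label(v) for v in keep}
        assert out.n_events == sum(
            1 for ev in net.events if set(ev.hyperlink) <= keep)


# ---------------------------------------------------------------------------
# inactivity-gap removal
# ---------------------------------------------------------------------------

def test_gap_removal_fixed_rule_reindexes():
    net = make_net([((0, 1), t) for t in (0, 1, 2, 5000, 5001)],
                   n_nodes=2, T=5002)
    out, report = hn.remove_inactivity_gaps(net, hn.GapRule("fixed", 1000))
    assert sorted(ev.t for ev in out.events) == [0, 1, 2, 3, 4]
    assert out.T == 5
    assert report.steps_removed == 4997
    assert report.gaps_removed == ((3, 4997),)


def test_gap_removal_no_gaps_is_identity(mixed_net):
    out, report = hn.remove_inactivity_gaps(
        mixed_net, hn.GapRule("fixed", mixed_net.T))
    assert set(out.events) == set(mixed_net.events)
    assert report.gaps_removed == ()


def test_gap_removal_preserves_event_count_and_short_gaps(rng):
    for _ in range(5):
        ts = sorted(rng.choice(500, size=30, replace=False))
        net = make_net([((0, 1), int(t)) for t in ts], n_nodes=2, T=500)
        out, report = hn.remove_inactivity_gaps(net, hn.GapRule("tukey", 3.0))
        assert out.n_events == net.n_events
        # inter-event times not spanning a removed gap are unchanged
        removed = {(s, s + length) for s, length in report.gaps_removed}
        old = sorted(ev.t for ev in net.events)
        new = sorted(ev.t for ev in out.events)
        for (a, b), (na, nb) in zip(zip(old, old[1:]), zip(new, new[1:])):
            if not any(a < s_end and b > s0 for s0, s_end in removed):
                assert b - a == nb - na


def test_gap_rule_validation():
    with pytest.raises(ValueError):
        hn.GapRule("median", 1.0)
    with pytest.raises(ValueError):
        hn.GapRule("quantile", 2.0)


def test_gap_removal_collapse_to_one_step():
    net = make_net([((0, 1), t) for t in (0, 100)], n_nodes=2, T=101)
    out, _ = hn.remove_inactivity_gaps(net, hn.GapRule("fixed", 10),
                                       collapse_to=1)
    assert sorted(ev.t for ev in out.events) == [0, 2]
    assert out.T == 3
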