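# hotnets

Temporal-topological characterization of **higher-order evolving networks**
(temporal hypergraphs): timestamped group interactions such as face-to-face
contacts or co-authorships, where an *event* is the activation of a
*hyperlink* — a set of `d ≥ 2` nodes — at a discrete time step.

The package is for network scientists who want to ask, of a stream of group
interactions: do events that are close in time also tend to be close in
topology, do nodes that join many groups of one size also join many groups of
another, and do group events cluster in time around their local neighbourhood?

## What it computes

Let `𝓗 = (𝓝, 𝓔)` be the event record, `G` the unweighted pairwise aggregated
graph (every event's node set projected to a clique), and `H` the weighted
aggregated hypergraph (hyperlink weight = activation count).

* **Event distance.** For events `e₁ = (h₁, t)`, `e₂ = (h₂, s)`:
  `η(e₁,e₂) = 0` if `h₁ = h₂`, else `1 + min over node pairs of the hop count
  δ(u,v) on G`. Temporal distance is `𝓣 = |t − s|`.
* **Distance–delay curves.** `μ_d(Δt)` is the mean `η` between an order-d
  event and an event of another order given `𝓣 < Δt`, normalized by the
  unconditional mean (so it tends to 1 as `Δt → ∞`); `ν_d(Δt)` is the
  same-order variant. The strength of the temporal–topological correlation is
  the least-squares slope `m` of the curve against `log₁₀ Δt` over its
  increasing part.
* **Randomized references.** Three order-targeted null models that randomize
  order-d events only: `𝓗¹_d` reshuffles their timestamps, `𝓗²_d` permutes
  whole activity series among order-d hyperlinks, `𝓗³_d` permutes series only
  among equal-weight hyperlinks. All preserve `H` and `G`.
* **Cross-order topology.** d-degree `k_d(v)`, d-strength `s_d(v)`,
  `ω_d = |𝓔_d| / |𝓛_d|`, 30-bin relation curves and the reference
  `s_d(v) = ω_d · k_d(v)`.
* **Egonetwork trains.** The egonetwork of an order-d hyperlink is itself
  plus all lower-order hyperlinks sharing a node; event *trains* on its
  aggregated activity series (maximal runs with inter-event gaps ≤ Δt) give
  the center-active train-size distribution `Pr[S*_d = s]`.
* **Construction.** SocioPatterns-style `tij` ingestion, per-step maximal
  clique promotion of contacts into group events, largest-component
  restriction, inactivity-gap removal, and the missing-link completion
  robustness variant (patching near-cliques of size > 3 missing one contact).
* **Synthetic generators.** Seeded networks with controllable locality,
  burstiness and planted cross-order temporal–topological coupling, including
  ground-truth manifests, for validation and negative/positive controls.

## Worked example

```python
import hotnets as hn

# a coupled synthetic network: order-3 anchor events spawn nearby order-2
# events a few steps later
net, spawns = hn.generate_coupled(hn.SynthConfig(seed=0, p_c=0.9))

curve = hn.distance_curve(net, d=3, kind="cross_order")
fit = hn.fit_increasing_slope(curve)
null = hn.randomize_H1(net, 3, seed=1)
null_fit = hn.fit_increasing_slope(hn.distance_curve(null, 3, "cross_order"))
print(f"slope m = {fit.m:.3f} (real), {null_fit.m:.3f} (timestamp shuffle)")

real = hn.train_size_distribution(net, d=3, delta_t=60).average_size
rand = hn.train_size_distribution(null, d=3, delta_t=60).average_size
print(f"mean center-active train size = {real:.2f} (real), {rand:.2f} (null)")
```

prints (exactly, for this seed):

```
slope m = 0.048 (real), -0.004 (timestamp shuffle)
mean center-active train size = 6.16 (real), 3.56 (null)
```

The positive slope says events of different orders that occur within a short
delay sit closer on `G` than average — the planted coupling; the timestamp
shuffle destroys it. Likewise the local trains around order-3 hyperlinks are
about 1.6× larger than in the randomized reference.

The same analyses are available from the shell:

```sh
hotnets synth --preset coupled --seed 0 --out net.tsv
hotnets distance-curve net.tsv curve.tsv --order 3 --kind cross
hotnets trains net.tsv out/ --order 3 --delta-t 60 --units steps
hotnets characterize run.yaml        # end-to-end pipeline from a YAML config
```

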