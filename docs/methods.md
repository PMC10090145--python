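# Methods

## Data model

A higher-order evolving network is a node set plus a set of events, each the
activation of a hyperlink (a set of `d ≥ 2` dense node ids) at an integer
step on `[0, T)`. Activity is binary per (hyperlink, step): duplicate records
collapse silently (counted in the log). External labels are preserved in a
node table so files round-trip. Two static views are derived once and reused:
the pairwise aggregated graph `G` (each event's node set becomes a clique —
for contact data this equals the raw pairwise aggregation, since group events
are themselves deduced from contact cliques; for other data it is the only
consistent base for hop counts), and the weighted aggregated hypergraph `H`
(weight = activation count).

**Time handling.** Raw timestamps are divided by the step length (given, or
inferred as the gcd of inter-record differences) and shifted so the first
event is at step 0; `T` is then the last event step + 1. The native
hyperevent TSV carries a `# T=... dt=... unit=...` header which the reader
honours, so write→read round-trips are exact; headerless files get the gcd
inference. Without the header, re-reading a file whose event steps share a
common divisor would rescale them — the header exists precisely to keep
round-trips the identity.

## Construction and preprocessing

* **Clique promotion.** Per step, the simultaneous-contact graph is
  decomposed into maximal cliques (Bron–Kerbosch via networkx); each maximal
  clique of size d becomes one order-d event, sub-cliques are dropped.
  Overlapping maximal cliques both become events. The output per step is an
  antichain whose 2-subsets reproduce the contact edges exactly.
* **Missing-link completion.** A measured contact stream may miss one pair
  of a genuine group of size > 3, splitting it into two (d−1)-cliques. Per
  step, every non-adjacent pair whose common neighbourhood contains at least
  one adjacent pair (i.e. some induced subgraph of size ≥ 4 is complete minus
  exactly that pair) gets the missing contact added, in a single pass, before
  re-promotion. Only maximal near-cliques matter conceptually, but any
  near-clique containing a non-edge misses exactly that non-edge, so the scan
  over non-edges adds the same edge set; the exhaustive-subset oracle test
  confirms this.
* **Largest component.** Nodes outside the largest connected component of
  `G` are dropped with their events (each event lies inside one component);
  size ties go to the component with the smallest original node id.
* **Inactivity gaps.** The network-wide activity series (events per step)
  defines maximal zero-activity runs; runs whose length is an outlier are
  deleted and the clock closed up. The default rule is a Tukey fence
  (length > Q3 + 3·IQR of the run-length distribution) — robust, and the
  least surprising reading of "outliers of the inter-event time
  distribution"; `quantile` and `fixed` rules are available, as is collapsing
  a gap to one step instead of zero. Event counts and all inter-event times
  not spanning a removed gap are preserved.

## Distance–delay analysis

`η` is computed per hyperlink pair (it does not depend on the timestamps) by
multi-source BFS from each order-d hyperlink's node set over an adjacency
list of `G`; event pairs then only need the delay histogram. The conditional
population at threshold `Δt` uses the strict inequality `𝓣 < Δt`; pairs are
unordered, counted once, self-pairs excluded, simultaneous pairs included for
every `Δt ≥ 1`. The default grid is 50 log-spaced integer thresholds from 1
to `T`, deduplicated. The normalization denominator is the unconditional mean
over the same pair population, so the curve reaches exactly 1 at any
threshold beyond the maximal delay + 1. Pair enumeration is exact below
2·10⁷ pairs (vectorized in chunks); above that a uniform pair sample
(default 10⁶, seed required) is used and per-point standard errors are
reported. Unreachable pairs (possible only before LCC restriction) are
excluded and counted.

`G` is fixed once from the *full* network before any null-model comparison;
the null models preserve it anyway, but reusing it avoids recomputation.

**Slope fit.** The normalized curve is regressed on `log₁₀(Δt · dt)` by least
squares over the window from the curve's argmin (ties broken toward the
largest index — in contact data the curve first dips because a group event
suppresses simultaneous sub-group events) to the last defined point. Fewer
than 3 points after the argmin triggers a flagged whole-curve fit. The slope
is per decade of delay, invariant to the `dt` scaling (which shifts only the
intercept).

## Randomized references

All three models touch order-d events only and preserve the order census,
`H`, `G`, and every other order's events bit-identically.

* `H1` permutes the multiset of order-d timestamps across those events.
  Collisions (a hyperlink assigned the same step twice) are repaired by
  random transpositions, up to a cap, after which the input is returned with
  a warning — collisions are rare in practice and impossible when all
  timestamps are distinct.
* `H2`/`H3` assign the order-d activity series to hyperlinks by one uniform
  permutation (`H3`: block-diagonal within equal-weight groups). A single
  uniform permutation is the stationary distribution of iterated random
  transpositions and is reproducible from one seed. `H3` degenerates to the
  identity when all weights are distinct — by design, the model's
  perturbation is small when few weight ties exist.

Statistics over null models are reported as means over independent
realizations (default 10) drawn from spawned seed streams.

## Topology and trains

Degree/strength tabulation is a single pass over `H`; the two sum identities
are asserted in tests on every generated and randomized instance. Binning:
30 bins, logarithmic (spanning [min positive normalized x, 1]) for the
cross-order curves, linear over the observed degree range for strength vs
degree; a point on an interior edge joins the left bin; empty bins are
emitted with count 0 and missing mean; single-occupant bins are kept. A
Spearman rank correlation over the doubly-active node set accompanies each
cross-order curve as a scalar summary of the visual trend.

Train detection scans the sorted active steps of an egonetwork's aggregated
series: gaps ≤ Δt (inclusive) join, larger gaps split. Inter-event times are
measured between consecutive active steps; simultaneity contributes size, not
gaps, and a train's size counts events with multiplicity. Default reference
intervals are 60 and 120 native units (seconds for contacts, days for
collaborations). Trains from overlapping egonetworks are pooled without
deduplication — the distribution is over per-center series. Egonetworks of
order 2 are permitted but are singletons (no strictly lower order exists).

## Synthetic generators and what they do (not) show

The generators define the study conditions used by the tests and the
acceptance script: n = 300 nodes, T = 5000 steps, 600 order-2 and 200
order-3 hyperlinks drawn on a ring lattice of radius 5 (so `G` has a
nontrivial diameter of a few tens of hops — uniform drawing would collapse
all distances to ~2), a mean of 3 activations per hyperlink (Poisson,
clipped to ≥ 1, times uniform without replacement).

* *Coupling* (positive control): each order-3 event spawns, with probability
  0.9, a batch of 1 + Poisson(2) order-2 events on hyperlinks sharing a node
  with it, each lagged by a geometric delay of mean 8 steps. This plants
  exactly the signature the cross-order curve measures (pairs at η ≤ 1 with
  small delay) at an effect size comparable to a clearly correlated
  empirical network, and produces ground-truth spawn records for oracle
  tests.
* *Burstiness*: per-hyperlink inter-event times drawn from a zeta law with
  exponent 2.2 (truncated at T/2), reflecting the fat-tailed inter-event
  times of real contact sequences. It drives the same-order effect: bursts
  of the same hyperlink give many η = 0 pairs at short delay, which the
  series-preserving models `H2`/`H3` keep and the timestamp shuffle `H1`
  destroys.
* *Contact fixtures*: planted node-disjoint cliques (sizes 2–5) and
  near-cliques (sizes 4–5 minus one edge) at known steps, with manifests.

What passing these tests shows: the statistics detect planted structure of
the kind they are defined to measure, and the null models destroy exactly
what they claim to. What it does not show: real contact data have circadian
rhythms, degree heterogeneity, correlated hyperlink overlap across orders
and non-stationary activity, none of which the generators emulate; absolute
slope or train-size values on real data will differ.

## Numerical choices and edge cases

* Problem sizes throughout the test-suite and acceptance runs are the
  defaults above with 10 seeds per stochastic contract (20 for the
  strength–degree diagonal check), chosen so the whole analysis battery is
  an exact, desk-scale computation.
* Grid points with an empty conditional population are emitted as missing
  with count 0, not interpolated.
* Degenerate binning inputs (all x equal) expand the bin span symmetrically
  so the single occupied bin is well defined.
* Empty networks round-trip and aggregate to empty structures; operations
  that need a population (`ω_d` without order-d hyperlinks, curves without
  pairs) raise instead of returning silent nans.
* Event-list order never matters: all aggregations and curves are invariant
  under permutation of events and relabeling of nodes (tested).

## Known limitations

* The exact pair enumeration is O(|𝓔_d| · |𝓔|) per curve; for large archives
  the sampled estimator is the intended path.
* H1's collision repair is a heuristic; for pathological inputs (one
  hyperlink owning nearly all order-d events at nearly all steps) it falls
  back to the identity with a warning rather than sampling uniformly from
  the constrained permutation set.
* Inactivity-gap removal operates on the network-wide series only; per-node
  or per-community inactivity is out of scope.
* The collaboration-network ingestion assumes author identities are already
  resolved; name disambiguation is a non-goal.
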