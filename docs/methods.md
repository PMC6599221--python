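# Methods

This note documents the models, the numerical choices and the synthetic-data
design behind `progchain`, including the points where the procedure was
genuinely open and a choice had to be made.

## Evidence layers

**Association network (ADN).** Each disease is a bit vector over proteins;
edge weight is the cosine similarity, which lies in [0, 1] and grows with the
number of shared proteins. Protein sharing is symmetric, so the ADN is
*bidirected*: every retained pair is emitted in both directions. Because
protein associations are abundant, the network is sparsified by k-nearest
neighbours before use: a pair survives when either endpoint ranks the other
among its `knn_k` most similar neighbours (union rule; ties at the k-th
similarity are all kept, so results do not depend on sort order). Union
semantics preserve the symmetry of the bidirected network; mutual-k-NN would
also be defensible but breaks fewer-neighbour nodes away from the graph.

**Pathway network (pDPN).** For a disease pair, the intersection of their
pathway gene sets is the *sharing block* S. The flow `F(i→j)` counts directed
gene reactions whose source gene belongs to disease i but not S and whose
target gene belongs to disease j's gene set. The raw weight is
`φ(F_ij − F_ji)·max(F_ij, F_ji)`: only the dominant direction keeps an edge,
ties yield none. The flow rule has admissible variants (e.g. following
reaction paths through the sharing block transitively); the implemented
single-step rule is the simplest reading and is pinned down by unit tests
with exhaustively enumerated reaction sets.

**Clinical network (cDPN).** From patient counts (total N, per-disease, and
per-pair co-occurrence), `RR(A,B) = p(B|A)/p(B|¬A)`. The direction of a pair
is decided by the ratio of relative risks `RRR(A,B) = RR(A,B)/RR(B,A)`; the
dominant direction's raw weight is the RRR itself (necessarily > 1). Two
guards are applied, both user-settable: pairs with fewer than
`min_pair_count` (default 50) co-occurring patients are skipped, and a
direction is only emitted when RRR exceeds `rrr_min` (default 1.05). The
guards exist because the raw definition assigns a direction to *every* pair —
sampling noise always makes the two RRs unequal — which floods the network
with arbitrary arrows. The defaults come from a null-calibration experiment:
at the synthetic default cohort size the null RRR standard deviation is about
0.003, so 1.05 is far outside noise while remaining below any genuine planted
signal. Setting `rrr_min=1.0, min_pair_count=0` restores the unguarded
definition. Pairs with undefined or infinite RR in either direction are
excluded and counted.

Note a property of RRR that shaped the synthetic design: for a 2×2
contingency table the odds ratio is exactly symmetric and RR nearly so, so
`RRR ≈ (1 − p(B|A)) / (1 − p(A|B))`. Conditional enrichment alone therefore
yields RRR ≈ 1; what moves RRR above 1 for A → B is A being more prevalent
than B — epidemiologically, a progression funnel in which each downstream
stage is rarer than its predecessor.

**Text network (tDPN).** Pre-extracted clause records (term, ordered disease
pair, document, clause count) are aggregated per term t and ordered pair into
a document–clause frequency `DCF_t = df·log(cf + 1)` (df documents, cf
clauses across them; `cf ≥ df` is enforced at ingest). Term strengths α_t
weight causal verbs above mere-association phrasing. The pair strength is
`s_ij = Σ_t α_t·DCF_t`, and the raw weight is the positive part of
`s_ij − s_ji`. The logarithm base is configurable and defaults to natural
log; the base only rescales raw weights, which are re-normalized anyway.

**Normalization.** pDPN, cDPN and tDPN raw weights are unbounded; each
network is divided by its own maximum raw weight, mapping weights to (0, 1]
with the strongest edge at exactly 1. Division by the maximum is monotone,
preserves zeros, and needs no distributional assumptions. Its known cost is
contrast compression when raw values cluster (one outlying maximum deflates
every other edge); this matters for the synthetic design below.

## Integration and distances

The integrated network's node set is the union of the layers' node sets; an
edge present in at least one layer is kept with weight pooled by
`combine_rule` over the available per-layer weights (each scaled by an
optional per-source weight, all sources equal by default). The default rule
is `max` — keep the strongest evidence — because it stays within [0, 1]
without renormalization; `mean` is provided as an alternative. Edges whose
only support is the ADN carry no direction of their own and are multiplied by
the penalty factor β (default 0.5, configurable); an edge with any directed
evidence is untouched by β. The penalty is applied in weight space, before
the distance transform, so all quantities keep their [0, 1] semantics.

Search distances are `dist = 1 − w`. Zero-distance arcs (weight exactly 1)
are legal; the search never revisits a node, so zero-cost cycles cannot trap
it (a dedicated fixture exercises this).

## Chain search

One Dijkstra pass over the arc-reversed graph from the target stores the
exact optimal remaining distance h(v) for every node (∞ when the target is
unreachable). Forward A* uses `f(v) = g(v) + h(v)`; because h is exact it is
admissible and consistent, so nodes never need reopening and the first path
found is optimal. With h ≡ 0 the expansion order provably reduces to plain
Dijkstra's, which the tests check against an independent implementation.

Subsequent chains come from a deviation loop: for each position j along the
latest chain, the prefix up to j is fixed as a root, the arcs that previously
found chains take out of that same root are cut, the root's interior nodes
are banned, and A* re-searches from the branch point to the target.
Candidates that duplicate an earlier chain are discarded; the rest persist in
a pool across iterations, and each iteration promotes the pool's best. The
loop stops at k chains or when the pool is empty. A plain "cut one arc of
the previous chain and re-search from the source" scheme was considered and
rejected: whenever the graph holds three or more arc-disjoint routes, every
single-arc cut leaves the already-known best route intact, so all candidates
are duplicates and the loop stalls after two chains. With root-prefix
deviation and non-negative distances the returned list is an exact
shortest-first prefix of the loop-free path enumeration, which the test suite
asserts against an exhaustive oracle on small random digraphs.

The heuristic is *not* recomputed after cuts: removing arcs can only lengthen
shortest paths, so the full-graph h remains a lower bound. This reuse is the
method's efficiency point — one Dijkstra per target, many A* runs.

Determinism: frontier ties on f break by lower g, then fewer hops, then node
id; equal-distance candidate chains order by fewer hops, then lexicographic
disease sequence. Identical inputs give identical chain sets.

**Progression score.** `PS = δ·exp(−l + Σw)` over a chain's integrated arc
weights. Since every w ≤ 1, PS decreases with chain length; it equals δ for a
perfect direct link. δ merely scales the score and defaults to 100, which
puts typical strong chains in the tens.

## Validation against clinical history

Chains built from an integration that excludes the clinical layer are scored
against the held-out comorbidity table: each consecutive pair with defined,
finite RRs contributes `RRR(i, j)`; the relation is supported when RRR > 1
(strictly — an exact tie counts against), and a chain is supported when the
arithmetic mean of its defined per-arc RRRs exceeds 1. Pairs without
evaluable clinical records are skipped and reported, not counted as failures,
since RRR is simply not defined for them. No `rrr_min` guard applies here:
validation asks about the direction of evidence, not edge existence.

## Synthetic worlds

`simulate_world` plants a progression DAG — by default a partition of the 30
diseases into disjoint directed chains of 3 edges, emulating independent
progression sequences — and emits all four raw evidence layers:

* **Proteins** (ADN): each disease draws 12 of 150 proteins; a planted
  successor inherits each of its predecessor's current proteins with
  probability 0.6, processed in topological order so overlap decays
  geometrically with planted distance.
* **Pathways** (pDPN): each disease draws 10 of 300 genes; each planted edge
  contributes a 2-gene sharing block and exactly 10 distinct reactions from
  predecessor-exclusive genes into the successor's gene set, plus occasional
  reverse reactions (Poisson, mean 0.5) and 5 global noise reactions. The
  per-edge reaction count is deliberately constant: under divide-by-max
  normalization, count jitter would let one outlying edge deflate all others
  and blur the planted structure; a constant count is the operational meaning
  of "uniformly strong pathway evidence".
* **Clinical history** (cDPN): 200,000 patients are sampled
  disease-by-disease in topological order. A disease at planted depth d has
  base incidence `0.16 · 0.5^d`; carrying any planted predecessor multiplies
  the incidence by `rr_effect` (default 5, capped at 0.8). The depth decay is
  the progression funnel discussed above — without it, RR near-symmetry makes
  the planted direction invisible to RRR no matter how strong the
  conditional enrichment.
* **Text** (tDPN): each planted edge receives 1 + Poisson(4) documents in the
  planted orientation (causal-strength terms) and Poisson(0.5) reverse
  documents; clause counts are 1 + Poisson(1); 5 noise documents land on
  random non-planted ordered pairs. A `text_symmetric` switch equalizes the
  two orientations for null experiments.

One integer seed drives a named, independent substream per layer, so changing
one layer's parameters never perturbs another layer's draws, and equal seeds
give byte-identical serialized worlds.

What the generator does *not* emulate: real nosology or term vocabularies,
overlapping progression pathways (default chains are disjoint), confounding
by shared risk factors, reporting bias in the literature layer, and
diagnosis-code noise in claims data. Recovery results on these worlds
demonstrate that the pipeline detects the signal it defines, under strong and
clean effects at small scale — not performance on real clinical data.

Measured at the defaults (20 seeds): clinical direction recovery of planted
edges ≈ 1.0, exact end-to-end recovery of planted length-3 chains ≈ 0.99,
spurious directed edges under a null world (rr_effect = 1, symmetric text)
0% (cDPN) and ≈ 3% (tDPN) of ordered pairs. These numbers are recomputed,
not quoted, by `scripts/acceptance.py` and the acceptance tests.

## Problem sizes and numerics

The test and acceptance workloads use 30-disease worlds, 200,000-patient
cohorts, 200 random digraphs of 6–12 nodes for search-exactness checks
(exhaustive loop-free enumeration is the oracle) and 100 9-node digraphs for
k-shortest prefix checks — sizes chosen so every oracle is exact and the full
suite runs in well under a minute. Floating-point comparisons in tests use
1e-12 for closed-form formulas and 1e-9 for accumulated path distances. Edge
weights serialize via `repr`, so TSV round-trips are bit-exact.

## Known limitations

* The k-NN rule for the ADN (union vs mutual) and the single-step flow rule
  for the pDPN are each one admissible reading of their definitions.
* Divide-by-max normalization makes all weights relative to a single extreme
  edge; a robust quantile could be substituted where real data contain
  outliers.
* The cDPN guards trade recall for precision; with small cohorts the defaults
  may suppress genuine directions.
* Per-source integration weights are exposed but default to equal; learning
  them from data is out of scope.
* Chain search returns loop-free paths only; cyclic progression (relapse) is
  outside the model.
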