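"""k-shortest progression-chain search.

The search pipeline mirrors the method it implements:

1. Run Dijkstra on the arc-reversed distance graph from the *target*
   disease, giving the exact optimal remaining distance h(v) for every
   node.  Because h is exact it is both admissible and consistent, so
   the subsequent A* runs are optimal without reopening.
2. Run forward A* with f(v) = g(v) + h(v) to obtain the best chain.
3. For the i-th chain, branch off every position of the previous
   chain: cut the arcs earlier chains take out of the shared prefix,
   re-run A* from the branch point on the reduced graph (h stays
   admissible: removing arcs can only lengthen paths), pool the
   candidate paths, discard duplicates of earlier chains, and keep
   the shortest as the next chain.  Stop after k chains or when no
   candidate exists.

Chains are scored with the progression score
``PS = delta * exp(-l + sum(w))`` where l is the edge count and w the
integrated (not distance) weights; PS decreases with chain length, so
shorter, stronger chains rank higher.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from heapq import heappop, heappush
from typing import Iterable, Sequence

import pandas as pd

from .netcore import DistanceGraph, ProgressionNetwork, logger

__all__ = [
    "HeuristicTable",
    "ProgressionChain",
    "ChainSet",
    "ScoreParams",
    "reverse_dijkstra",
    "astar",
    "k_shortest_chains",
    "progression_score",
    "chain_spectrum",
]

#: Optimal remaining distance to the target per node (inf = unreachable).
HeuristicTable = dict[str, float]


@dataclass
class ProgressionChain:
    """An ordered, loop-free disease path with its arc weights."""

    diseases: tuple[str, ...]
    edge_weights: tuple[float, ...]
    total_distance: float
    score: float | None = None

    def __post_init__(self) -> None:
        if len(self.diseases) < 2:
            raise ValueError("a progression chain needs at least two diseases")
        if len(set(self.diseases)) != len(self.diseases):
            raise ValueError(f"chain revisits a disease: {self.diseases}")
        if len(self.edge_weights) != len(self.diseases) - 1:
            raise ValueError("edge_weights length must be len(diseases) - 1")

    @property
    def length(self) -> int:
        """Number of arcs l in the chain."""
        return len(self.edge_weights)

    @property
    def sum_weights(self) -> float:
        return sum(self.edge_weights)

    def sort_key(self) -> tuple[float, int, tuple[str, ...]]:
        return (self.total_distance, self.length, self.diseases)


@dataclass
class ChainSet:
    """Up to k chains sorted by ascending total distance.

    ``candidate_pools[i]`` keeps the deviation candidates examined when
    chain i+2 was selected (for audit).
    """

    chains: list[ProgressionChain] = field(default_factory=list)
    candidate_pools: list[list[ProgressionChain]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.chains)

    def __iter__(self):
        return iter(self.chains)


@dataclass(frozen=True)
class ScoreParams:
    """Scale constant delta of the progression score."""

    delta: float = 100.0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be > 0")


def reverse_dijkstra(g: DistanceGraph, target: str) -> HeuristicTable:
    """Exact shortest distance from every node *to* the target.

    Runs Dijkstra over the arc-reversed graph starting at ``target``;
    nodes that cannot reach the target map to +inf.
    """
    if target not in g.nodes:
        raise KeyError(f"target {target!r} not in graph")
    h: HeuristicTable = {n: math.inf for n in g.nodes}
    h[target] = 0.0
    done: set[str] = set()
    heap: list[tuple[float, str]] = [(0.0, target)]
    while heap:
        d, node = heappop(heap)
        if node in done:
            continue
        done.add(node)
        for u, arc_d in g.predecessors(node):
            nd = d + arc_d
            if nd < h[u]:
                h[u] = nd
                heappush(heap, (nd, u))
    return h


def _chain_from_path(path: Sequence[str], g: DistanceGraph) -> ProgressionChain:
    weights = tuple(1.0 - g.arcs[(u, v)] for u, v in zip(path, path[1:]))
    dist = sum(g.arcs[(u, v)] for u, v in zip(path, path[1:]))
    return ProgressionChain(tuple(path), weights, dist)


def astar(
    g: DistanceGraph,
    source: str,
    target: str,
    h: HeuristicTable,
    banned_arcs: frozenset[tuple[str, str]] = frozenset(),
    banned_nodes: frozenset[str] = frozenset(),
    trace: list[str] | None = None,
) -> ProgressionChain | None:
    """Minimum-distance loop-free path via A*, or None if unreachable.

    ``h`` must be admissible for ``g`` — guaranteed when it comes from
    :func:`reverse_dijkstra` on ``g`` or on any supergraph of its arc
    set (so the one heuristic can be reused across arc cuts).  With
    ``h`` identically zero the expansion order reduces to Dijkstra's.

    Frontier ties on f are broken by lower g, then fewer hops, then
    node id, making results deterministic.  ``trace``, if given, is
    appended with nodes in expansion (settle) order.
    """
    for endpoint in (source, target):
        if endpoint not in g.nodes:
            raise KeyError(f"node {endpoint!r} not in graph")
    if source == target:
        raise ValueError("source and target must differ (no zero-length chains)")
    if math.isinf(h.get(source, math.inf)):
        return None

    g_score: dict[str, float] = {source: 0.0}
    parent: dict[str, str] = {}
    hops: dict[str, int] = {source: 0}
    closed: set[str] = set()
    heap: list[tuple[float, float, int, str]] = [(h[source], 0.0, 0, source)]
    while heap:
        f, gd, nh, node = heappop(heap)
        if node in closed or gd > g_score.get(node, math.inf):
            continue
        closed.add(node)
        if trace is not None:
            trace.append(node)
        if node == target:
            path = [node]
            while path[-1] != source:
                path.append(parent[path[-1]])
            path.reverse()
            return _chain_from_path(path, g)
        for v, arc_d in g.successors(node):
            if v in closed or v in banned_nodes or (node, v) in banned_arcs:
                continue
            hv = h.get(v, math.inf)
            if math.isinf(hv):
                continue
            nd = gd + arc_d
            if nd < g_score.get(v, math.inf) or (
                nd == g_score.get(v) and nh + 1 < hops.get(v, math.inf)
            ):
                g_score[v] = nd
                parent[v] = node
                hops[v] = nh + 1
                heappush(heap, (nd + hv, nd, nh + 1, v))
    return None


def k_shortest_chains(
    g: DistanceGraph,
    source: str,
    target: str,
    k: int,
    h: HeuristicTable | None = None,
) -> ChainSet:
    """The k most plausible chains via an arc-cut deviation loop.

    Deviations branch off each position of the latest chain: the arcs
    that earlier chains take out of the shared prefix are cut, the
    prefix nodes are banned (loop-freeness), and A* re-searches from
    the branch point with the *same* heuristic computed once on the
    full graph (cuts only lengthen paths, so it stays admissible).
    Candidates that duplicate an earlier chain are discarded; surviving
    candidates persist across iterations, and the loop stops after k
    chains or when no candidate remains.  With non-negative distances
    this enumerates loop-free paths in exact shortest-first order.
    Ties break by fewer hops, then the lexicographic disease sequence.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if h is None:
        h = reverse_dijkstra(g, target)
    result = ChainSet()
    first = astar(g, source, target, h)
    if first is None:
        logger.info("no progression chain from %r to %r", source, target)
        return result
    result.chains.append(first)

    seen: set[tuple[str, ...]] = {first.diseases}
    pool: dict[tuple[str, ...], ProgressionChain] = {}
    while len(result.chains) < k:
        prev = result.chains[-1].diseases
        fresh: list[ProgressionChain] = []
        for j in range(len(prev) - 1):
            root = prev[: j + 1]
            banned_arcs = {
                (seq[j], seq[j + 1])
                for seq in seen
                if len(seq) > j + 1 and seq[: j + 1] == root
            }
            spur = astar(
                g,
                root[-1],
                target,
                h,
                banned_arcs=frozenset(banned_arcs),
                banned_nodes=frozenset(root[:-1]),
            )
            if spur is not None:
                diseases = root[:-1] + spur.diseases
                if diseases not in seen and diseases not in pool:
                    chain = _chain_from_path(diseases, g)
                    pool[diseases] = chain
                    fresh.append(chain)
        result.candidate_pools.append(
            sorted(fresh, key=ProgressionChain.sort_key)
        )
        if not pool:
            break
        best = min(pool.values(), key=ProgressionChain.sort_key)
        del pool[best.diseases]
        result.chains.append(best)
        seen.add(best.diseases)

    result.chains.sort(key=ProgressionChain.sort_key)
    return result


def progression_score(c: ProgressionChain, p: ScoreParams = ScoreParams()) -> float:
    """PS = delta * exp(-l + sum of integrated weights); stored on the chain."""
    if c.length < 1:
        raise ValueError("cannot score an empty chain")
    c.score = p.delta * math.exp(-c.length + c.sum_weights)
    return c.score


def chain_spectrum(
    g: DistanceGraph,
    net: ProgressionNetwork,
    target: str,
    sources: Iterable[str],
    k: int = 1,
    p: ScoreParams = ScoreParams(),
) -> pd.DataFrame:
    """Scored chains reaching one target from many sources.

    One reverse Dijkstra from the target is shared across all sources.
    Rows are sorted by progression score, descending; sources that
    cannot reach the target (or equal it) are omitted with a logged
    count.  Weights for scoring are looked up in ``net``.
    """
    sources = list(sources)
    if not sources:
        raise ValueError("need at least one source disease")
    h = reverse_dijkstra(g, target)
    rows = []
    skipped = 0
    for source in sources:
        if source == target or math.isinf(h.get(source, math.inf)):
            skipped += 1
            continue
        chains = k_shortest_chains(g, source, target, k, h=h)
        for rank, chain in enumerate(chains, start=1):
            weights = [
                net.weight(u, v) for u, v in zip(chain.diseases, chain.diseases[1:])
            ]
            scored = ProgressionChain(
                chain.diseases, tuple(weights), chain.total_distance
            )
            progression_score(scored, p)
            rows.append(
                {
                    "source": source,
                    "target": target,
                    "rank": rank,
                    "chain": "|".join(scored.diseases),
                    "length_l": scored.length,
                    "sum_weights": scored.sum_weights,
                    "total_distance": scored.total_distance,
                    "progression_score": scored.score,
                }
            )
    if skipped:
        logger.info("spectrum: %d sources could not reach %r", skipped, target)
    frame = pd.DataFrame(
        rows,
        columns=[
            "source",
            "target",
            "rank",
            "chain",
            "length_l",
            "sum_weights",
            "total_distance",
            "progression_score",
        ],
    )
    return frame.sort_values(
        "progression_score", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
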