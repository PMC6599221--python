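"""Core graph model for disease progression networks.

A progression network is a simple directed graph over disease identifiers.
Each arc carries a weight in [0, 1] (strength of the prior-posterior
relation) and a provenance set recording which evidence layer(s) support
it: ``ADN`` (protein-sharing association), ``pDPN`` (pathway flow),
``cDPN`` (clinical relative risk) or ``tDPN`` (literature mentions).

For path search, weights are turned into distances with
``dist(u, v) = 1 - w(u, v)``, so the strongest relations are the
shortest arcs.
"""

from __future__ import annotations

import csv
import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple

import yaml

logger = logging.getLogger("progchain")

#: Recognised provenance tags, in canonical order.
PROVENANCE_TAGS = ("ADN", "pDPN", "cDPN", "tDPN")


class Edge(NamedTuple):
    """A directed relation: weight in [0, 1] plus its evidence layers."""

    weight: float
    provenance: frozenset[str]


def _check_node_id(node: str) -> str:
    if not isinstance(node, str) or not node.strip():
        raise ValueError(f"invalid disease id: {node!r}")
    return node


class ProgressionNetwork:
    """Simple directed graph of diseases with weighted, tagged arcs.

    Isolated nodes are allowed: the node set may exceed the set of
    edge endpoints (density always uses the full node count).
    """

    def __init__(self) -> None:
        self.nodes: set[str] = set()
        self.edges: dict[tuple[str, str], Edge] = {}
        self._succ: dict[str, set[str]] = {}

    # -- construction -------------------------------------------------

    def add_node(self, node: str) -> None:
        self.nodes.add(_check_node_id(node))

    def add_edge(
        self,
        u: str,
        v: str,
        weight: float,
        provenance: Iterable[str],
    ) -> None:
        _check_node_id(u)
        _check_node_id(v)
        if u == v:
            raise ValueError(f"self-loop not allowed: {u!r}")
        w = float(weight)
        if not 0.0 <= w <= 1.0:
            raise ValueError(f"weight {w} outside [0, 1] on edge ({u!r}, {v!r})")
        prov = frozenset(provenance)
        if not prov:
            raise ValueError(f"empty provenance on edge ({u!r}, {v!r})")
        self.nodes.add(u)
        self.nodes.add(v)
        self.edges[(u, v)] = Edge(w, prov)
        self._succ.setdefault(u, set()).add(v)

    # -- queries -------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def successors(self, u: str) -> set[str]:
        return self._succ.get(u, set())

    def weight(self, u: str, v: str) -> float:
        return self.edges[(u, v)].weight

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.edges

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProgressionNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def copy(self) -> "ProgressionNetwork":
        out = ProgressionNetwork()
        out.nodes = set(self.nodes)
        out.edges = dict(self.edges)
        out._succ = {u: set(vs) for u, vs in self._succ.items()}
        return out

    def validate(self) -> None:
        """Re-check all type invariants; raise ValueError on violation."""
        for (u, v), e in self.edges.items():
            if u == v:
                raise ValueError(f"self-loop ({u!r})")
            if not 0.0 <= e.weight <= 1.0:
                raise ValueError(f"weight {e.weight} outside [0,1] on ({u}, {v})")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"dangling endpoint on ({u}, {v})")
            if not e.provenance:
                raise ValueError(f"empty provenance on ({u}, {v})")


@dataclass
class DistanceGraph:
    """Search-ready view of a network: ``dist = 1 - effective weight``.

    ``penalty_factor`` records the association-edge penalty that was in
    force when the distances were derived (1.0 means no penalty).
    """

    nodes: set[str]
    arcs: dict[tuple[str, str], float]
    penalty_factor: float = 1.0
    _succ: dict[str, list[tuple[str, float]]] = field(default_factory=dict, repr=False)
    _pred: dict[str, list[tuple[str, float]]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        succ: dict[str, list[tuple[str, float]]] = {}
        pred: dict[str, list[tuple[str, float]]] = {}
        for (u, v), d in self.arcs.items():
            if d < 0:
                raise ValueError(f"negative distance {d} on arc ({u}, {v})")
            succ.setdefault(u, []).append((v, d))
            pred.setdefault(v, []).append((u, d))
        # Sorted adjacency makes every traversal order deterministic.
        for adj in (succ, pred):
            for lst in adj.values():
                lst.sort()
        self._succ = succ
        self._pred = pred

    def successors(self, u: str) -> list[tuple[str, float]]:
        return self._succ.get(u, [])

    def predecessors(self, v: str) -> list[tuple[str, float]]:
        return self._pred.get(v, [])

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)


@dataclass(frozen=True)
class NetworkStats:
    """Summary statistics of a progression network.

    Clustering, components, diameter and radius are computed on the
    undirected projection (see the methods note); diameter and radius
    use the hop-count metric on the largest component.
    """

    n_nodes: int
    n_edges: int
    density: float
    clustering_coefficient: float
    n_components: int
    diameter: int
    radius: int
    avg_neighbors: float


def weight_to_distance(w: float, edge: tuple[str, str] | None = None) -> float:
    """Transform a relation weight in [0, 1] into a search distance 1 - w."""
    w = float(w)
    if not 0.0 <= w <= 1.0:
        where = f" on edge {edge}" if edge is not None else ""
        raise ValueError(f"weight {w} outside [0, 1]{where}")
    return 1.0 - w


def density(n_nodes: int, n_edges: int) -> float:
    """Density of a simple directed graph: m / (n * (n - 1))."""
    if n_nodes < 2:
        return 0.0
    return n_edges / (n_nodes * (n_nodes - 1))


def _undirected_adjacency(net: ProgressionNetwork) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {n: set() for n in net.nodes}
    for u, v in net.edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def _bfs_eccentricity(adj: Mapping[str, set[str]], start: str) -> tuple[int, set[str]]:
    """Hop eccentricity of ``start`` and the set of reached nodes."""
    seen = {start}
    frontier = deque([(start, 0)])
    ecc = 0
    while frontier:
        node, d = frontier.popleft()
        ecc = max(ecc, d)
        for nb in adj[node]:
            if nb not in seen:
                seen.add(nb)
                frontier.append((nb, d + 1))
    return ecc, seen


def network_stats(net: ProgressionNetwork) -> NetworkStats:
    """Compute summary statistics for a non-empty network."""
    if net.n_nodes == 0:
        raise ValueError("cannot compute statistics of an empty network")
    adj = _undirected_adjacency(net)

    # Watts-Strogatz local clustering averaged over all nodes; nodes
    # with undirected degree < 2 contribute 0.
    total_c = 0.0
    for node, nbrs in adj.items():
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(len(adj[nb] & nbrs) for nb in nbrs) // 2
        total_c += 2.0 * links / (k * (k - 1))
    clustering = total_c / net.n_nodes

    # Weakly connected components via BFS on the undirected projection.
    remaining = set(net.nodes)
    components: list[set[str]] = []
    while remaining:
        start = next(iter(remaining))
        _, comp = _bfs_eccentricity(adj, start)
        components.append(comp)
        remaining -= comp
    largest = max(components, key=len)

    if len(largest) > 1:
        sub = {n: adj[n] & largest for n in largest}
        eccs = [_bfs_eccentricity(sub, n)[0] for n in sorted(largest)]
        diam, rad = max(eccs), min(eccs)
    else:
        diam = rad = 0

    avg_neighbors = sum(len(v) for v in adj.values()) / net.n_nodes

    return NetworkStats(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        density=density(net.n_nodes, net.n_edges),
        clustering_coefficient=clustering,
        n_components=len(components),
        diameter=diam,
        radius=rad,
        avg_neighbors=avg_neighbors,
    )


# -- file I/O ----------------------------------------------------------

_EDGE_HEADER = ["source", "target", "weight", "provenance"]


def write_edge_list(net: ProgressionNetwork, path: str | Path) -> None:
    """Serialize a network as a TSV edge list (full float precision)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_EDGE_HEADER)
        for (u, v) in sorted(net.edges):
            e = net.edges[(u, v)]
            writer.writerow([u, v, repr(e.weight), ",".join(sorted(e.provenance))])


def read_edge_list(path: str | Path, dialect: str = "tsv") -> ProgressionNetwork:
    """Parse a TSV edge list into a network, validating every row."""
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    net = ProgressionNetwork()
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _EDGE_HEADER:
            raise ValueError(
                f"{path}: expected header {_EDGE_HEADER}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(row)}")
            u, v, w_str, prov_str = row
            try:
                w = float(w_str)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad weight {w_str!r}") from exc
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"{path}:{lineno}: weight {w} outside [0, 1]")
            if (u, v) in net.edges:
                raise ValueError(f"{path}:{lineno}: duplicate directed edge ({u}, {v})")
            prov = [p for p in prov_str.split(",") if p]
            try:
                net.add_edge(u, v, w, prov)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return net


def write_node_list(nodes: Iterable[str], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id"])
        for n in sorted(nodes):
            writer.writerow([n])


def read_node_list(path: str | Path) -> list[str]:
    with Path(path).open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if not header or header[0] != "id":
            raise ValueError(f"{path}: expected node-list header starting with 'id'")
        return [row[0] for row in reader if row]


CHAIN_HEADER = [
    "rank",
    "source",
    "target",
    "chain",
    "length_l",
    "sum_weights",
    "progression_score",
]


def write_chains_tsv(rows: Iterable[Mapping[str, object]], path: str | Path) -> None:
    """Write scored chains; ``chain`` is the pipe-joined disease sequence."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CHAIN_HEADER)
        for row in rows:
            writer.writerow([row[col] for col in CHAIN_HEADER])


def read_chains_tsv(path: str | Path) -> list[dict[str, object]]:
    out: list[dict[str, object]] = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != CHAIN_HEADER:
            raise ValueError(f"{path}: expected chain header {CHAIN_HEADER}")
        for row in reader:
            out.append(
                {
                    "rank": int(row["rank"]),
                    "source": row["source"],
                    "target": row["target"],
                    "chain": tuple(row["chain"].split("|")),
                    "length_l": int(row["length_l"]),
                    "sum_weights": float(row["sum_weights"]),
                    "progression_score": float(row["progression_score"]),
                }
            )
    return out


# -- configuration -----------------------------------------------------


@dataclass
class Config:
    """Run configuration shared by the CLI subcommands."""

    knn_k: int = 40
    penalty_factor: float = 0.5
    delta: float = 100.0
    log_base: float | None = None  # None -> natural log
    combine_rule: str = "max"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if not 0.0 < self.penalty_factor <= 1.0:
            raise ValueError("penalty_factor must lie in (0, 1]")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.combine_rule not in ("max", "mean"):
            raise ValueError("combine_rule must be 'max' or 'mean'")


def load_config(path: str | Path) -> Config:
    with Path(path).open() as fh:
        data = yaml.safe_load(fh) or {}
    known = {f for f in Config.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return Config(**data)
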