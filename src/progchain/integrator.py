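"""Integration of evidence-layer networks into one progression network.

The four layers are merged edge-wise: every directed pair present in at
least one layer appears in the integrated network, its weight pooled by
a combine rule (``max`` by default) over the available per-layer
weights.  Edges supported *only* by the association layer (ADN) carry
no direction of their own, so they are penalized by a factor beta in
(0, 1] before path search; any edge with a second, directed evidence
layer is left untouched by beta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .netcore import DistanceGraph, ProgressionNetwork, weight_to_distance


@dataclass
class IntegrationConfig:
    """Pooling rule, per-source weights and association penalty beta."""

    combine_rule: str = "max"
    source_weights: dict[str, float] = field(default_factory=dict)
    penalty_factor: float = 0.5

    def __post_init__(self) -> None:
        if self.combine_rule not in ("max", "mean"):
            raise ValueError("combine_rule must be 'max' or 'mean'")
        if not 0.0 < self.penalty_factor <= 1.0:
            raise ValueError("penalty_factor must lie in (0, 1]")
        for tag, w in self.source_weights.items():
            if w < 0:
                raise ValueError(f"source weight for {tag!r} must be >= 0")


def integrate(
    nets: list[tuple[str, ProgressionNetwork]],
    cfg: IntegrationConfig | None = None,
) -> ProgressionNetwork:
    """Merge tagged networks into the integrated progression network."""
    cfg = cfg or IntegrationConfig()
    if not nets:
        raise ValueError("need at least one network to integrate")
    tags = [tag for tag, _ in nets]
    if len(set(tags)) != len(tags):
        raise ValueError(f"duplicate network tags: {tags}")

    all_nodes: set[str] = set()
    for _, net in nets:
        all_nodes |= net.nodes
    if not all_nodes:
        raise ValueError("integration of empty networks")

    # Collect per-edge contributions (scaled by source weight).
    contrib: dict[tuple[str, str], dict[str, float]] = {}
    for tag, net in nets:
        scale = cfg.source_weights.get(tag, 1.0)
        for pair, edge in net.edges.items():
            contrib.setdefault(pair, {})[tag] = min(edge.weight * scale, 1.0)

    out = ProgressionNetwork()
    for n in all_nodes:
        out.add_node(n)
    for pair, by_tag in contrib.items():
        weights = list(by_tag.values())
        if cfg.combine_rule == "max":
            w = max(weights)
        else:
            w = sum(weights) / len(weights)
        provenance = frozenset(by_tag)
        if provenance == {"ADN"}:
            w *= cfg.penalty_factor
        out.add_edge(pair[0], pair[1], min(w, 1.0), provenance)
    return out


def to_distance_graph(net: ProgressionNetwork, penalty_factor: float = 1.0) -> DistanceGraph:
    """Turn integrated weights into search distances dist = 1 - w."""
    net.validate()
    arcs = {
        pair: weight_to_distance(edge.weight, edge=pair)
        for pair, edge in net.edges.items()
    }
    return DistanceGraph(nodes=set(net.nodes), arcs=arcs, penalty_factor=penalty_factor)
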