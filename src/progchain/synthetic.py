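"""Synthetic evidence generator with a planted progression ground truth.

The generator plants a known progression DAG over artificial diseases
(by default a partition into disjoint directed chains, emulating
independent progression sequences) and emits all four raw evidence
layers consistent with it:

* proteins — each disease draws a base protein set; a planted
  successor inherits each of its predecessor's proteins with
  probability ``protein_share_decay``, so protein overlap (and hence
  association cosine) decays geometrically with planted distance;
* pathways — each planted edge contributes a small sharing block and
  directed reactions from predecessor-exclusive genes into the
  successor's gene set;
* clinical history — per-patient Bernoulli sampling in topological
  order: carrying a planted predecessor multiplies the successor's
  incidence by ``rr_effect``; base prevalence declines geometrically
  with planted depth (the progression funnel that gives the ratio of
  relative risks its direction);
* text — documents mentioning a planted pair appear predominantly in
  the planted orientation, with causal relation terms.

One integer seed drives an independent named substream per layer, so
changing one layer's parameters never perturbs another's draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .builders import (
    ComorbidityTable,
    DiseaseProteinMatrix,
    PathwayData,
    TermStrengthTable,
    TextEvidence,
    build_adn,
    build_cdpn,
    build_pdpn,
    build_tdpn,
)
from .netcore import DistanceGraph, ProgressionNetwork

__all__ = [
    "WorldParams",
    "SyntheticWorld",
    "simulate_world",
    "build_all_layers",
    "enumerate_loop_free_paths",
    "make_fixture",
    "FIXTURE_CATALOGUE",
]

_DEFAULT_TERMS = {
    "causes": 2.0,
    "leads_to": 1.8,
    "induces": 1.6,
    "precedes": 1.2,
    "associated_with": 0.4,
}

# Substream indices: one named stream per evidence layer.
_STREAMS = {"structure": 0, "proteins": 1, "pathways": 2, "clinical": 3, "text": 4}


@dataclass
class WorldParams:
    """Parameters of a synthetic progression world.

    Defaults describe a small but strongly signalled world: 30
    diseases in disjoint planted chains of 3 edges, 20,000 patients, a
    five-fold incidence enrichment along planted edges, and literature
    evidence concentrated in the planted orientation.
    """

    n_diseases: int = 30
    chain_length: int = 3  # edges per planted chain
    planted: list[tuple[str, str]] | None = None  # explicit DAG overrides
    # proteins / ADN
    n_proteins: int = 150
    proteins_per_disease: int = 12
    protein_share_decay: float = 0.6
    knn_k: int = 10
    # pathways / pDPN
    n_genes: int = 300
    genes_per_disease: int = 10
    shared_genes_per_edge: int = 2
    reactions_per_edge: int = 10
    noise_reactions: int = 5
    reverse_reaction_rate: float = 0.5
    # clinical / cDPN
    n_patients: int = 200_000
    base_prevalence: float = 0.16
    prevalence_decay: float = 0.5
    rr_effect: float = 5.0
    # text / tDPN
    docs_per_edge: float = 5.0
    reverse_doc_rate: float = 0.5
    noise_text_pairs: int = 5
    clause_rate: float = 2.0
    text_symmetric: bool = False
    terms: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_TERMS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_diseases < 2:
            raise ValueError("need at least two diseases")
        if not 0.0 < self.protein_share_decay < 1.0:
            raise ValueError("protein_share_decay must lie in (0, 1)")
        if not 0.0 < self.base_prevalence < 1.0:
            raise ValueError("base_prevalence must lie in (0, 1)")
        if not 0.0 < self.prevalence_decay <= 1.0:
            raise ValueError("prevalence_decay must lie in (0, 1]")
        if self.rr_effect < 1.0:
            raise ValueError("rr_effect must be >= 1")
        if self.rr_effect * self.base_prevalence > 0.95:
            raise ValueError(
                "infeasible incidence: rr_effect * base_prevalence exceeds 0.95"
            )
        if self.clause_rate <= 0 or self.docs_per_edge <= 0:
            raise ValueError("text rates must be positive")
        if self.planted is not None:
            _toposort([str(u) for u, _ in self.planted], self.planted)


def _toposort(
    nodes: Sequence[str], edges: Sequence[tuple[str, str]]
) -> list[str]:
    """Kahn topological sort; raises on cycles."""
    node_set = set(nodes) | {n for e in edges for n in e}
    out: dict[str, list[str]] = {n: [] for n in node_set}
    indeg: dict[str, int] = {n: 0 for n in node_set}
    for u, v in edges:
        if u == v:
            raise ValueError(f"planted self-loop {u!r}")
        out[u].append(v)
        indeg[v] += 1
    ready = sorted(n for n, d in indeg.items() if d == 0)
    order: list[str] = []
    while ready:
        n = ready.pop(0)
        order.append(n)
        for v in sorted(out[n]):
            indeg[v] -= 1
            if indeg[v] == 0:
                ready.append(v)
        ready.sort()
    if len(order) != len(node_set):
        raise ValueError("planted structure contains a cycle")
    return order


@dataclass
class SyntheticWorld:
    """All four raw evidence layers plus the planted truth."""

    params: WorldParams
    diseases: list[str]
    planted: list[tuple[str, str]]
    depths: dict[str, int]
    matrix: DiseaseProteinMatrix
    pathways: PathwayData
    comorbidity: ComorbidityTable
    text: TextEvidence
    alphas: TermStrengthTable

    def planted_paths(self, n_edges: int) -> list[tuple[str, ...]]:
        """All directed planted paths with exactly ``n_edges`` arcs."""
        succ: dict[str, list[str]] = {}
        for u, v in self.planted:
            succ.setdefault(u, []).append(v)
        paths: list[tuple[str, ...]] = []

        def extend(path: tuple[str, ...]) -> None:
            if len(path) == n_edges + 1:
                paths.append(path)
                return
            for nxt in sorted(succ.get(path[-1], [])):
                if nxt not in path:
                    extend(path + (nxt,))

        for d in self.diseases:
            extend((d,))
        return paths

    def planted_hops(self, a: str, b: str) -> int | None:
        """Shortest planted hop distance a -> b, or None if unreachable."""
        succ: dict[str, list[str]] = {}
        for u, v in self.planted:
            succ.setdefault(u, []).append(v)
        frontier = {a}
        seen = {a}
        hops = 0
        while frontier:
            if b in frontier:
                return hops
            hops += 1
            frontier = {v for u in frontier for v in succ.get(u, [])} - seen
            seen |= frontier
        return None

    def write(self, outdir: str | Path) -> None:
        """Serialize every layer in the TSV dialects the builders read."""
        import csv

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)

        def tsv(name: str, header: list[str], rows: list[list]) -> None:
            with (outdir / name).open("w", newline="") as fh:
                w = csv.writer(fh, delimiter="\t", lineterminator="\n")
                w.writerow(header)
                w.writerows(rows)

        assoc = [
            [self.matrix.diseases[i], self.matrix.proteins[j]]
            for i, j in zip(*np.nonzero(self.matrix.bits))
        ]
        tsv("associations.tsv", ["disease_id", "protein_id"], sorted(assoc))
        tsv(
            "pathway_membership.tsv",
            ["disease_id", "gene_id"],
            sorted([d, g] for d, gs in self.pathways.gene_sets.items() for g in gs),
        )
        tsv(
            "pathway_reactions.tsv",
            ["gene_from", "gene_to"],
            sorted(list(r) for r in self.pathways.reactions),
        )
        tsv("comorbidity_totals.tsv", ["n_total"], [[self.comorbidity.n_total]])
        tsv(
            "comorbidity_singles.tsv",
            ["disease_id", "count"],
            sorted([d, n] for d, n in self.comorbidity.n_single.items()),
        )
        tsv(
            "comorbidity_pairs.tsv",
            ["disease_a", "disease_b", "count"],
            sorted([a, b, n] for (a, b), n in self.comorbidity.n_pair.items()),
        )
        tsv(
            "text_evidence.tsv",
            ["term", "source_disease", "target_disease", "document_id", "clause_count"],
            sorted(list(r) for r in self.text.records),
        )
        tsv(
            "term_strengths.tsv",
            ["term", "alpha"],
            sorted([t, a] for t, a in self.alphas.strength.items()),
        )
        tsv("truth_edges.tsv", ["source", "target"], sorted(list(e) for e in self.planted))


def _rng(p: WorldParams, layer: str) -> np.random.Generator:
    return np.random.default_rng([p.seed, _STREAMS[layer]])


def simulate_world(p: WorldParams) -> SyntheticWorld:
    """Generate a complete synthetic world; deterministic given the seed."""
    diseases = [f"D{i:03d}" for i in range(p.n_diseases)]

    # --- planted structure -------------------------------------------
    rng = _rng(p, "structure")
    if p.planted is not None:
        planted = [(str(u), str(v)) for u, v in p.planted]
        order = _toposort(diseases, planted)
    else:
        shuffled = list(diseases)
        rng.shuffle(shuffled)
        planted = []
        span = p.chain_length + 1
        for start in range(0, p.n_diseases - span + 1, span):
            block = shuffled[start : start + span]
            planted.extend(zip(block, block[1:]))
        order = _toposort(diseases, planted)
    preds: dict[str, list[str]] = {d: [] for d in order}
    for u, v in planted:
        preds[v].append(u)
    depths: dict[str, int] = {}
    for d in order:
        depths[d] = max((depths[u] + 1 for u in preds[d]), default=0)

    # --- proteins -----------------------------------------------------
    rng = _rng(p, "proteins")
    proteins = [f"P{i:03d}" for i in range(p.n_proteins)]
    protein_sets: dict[str, set[str]] = {}
    for d in diseases:
        picks = rng.choice(p.n_proteins, size=p.proteins_per_disease, replace=False)
        protein_sets[d] = {proteins[i] for i in picks}
    for u, v in sorted(planted, key=lambda e: (depths[e[0]], e)):
        inherited = [
            prot
            for prot in sorted(protein_sets[u])
            if rng.random() < p.protein_share_decay
        ]
        protein_sets[v] |= set(inherited)
    bits = np.zeros((p.n_diseases, p.n_proteins), dtype=np.uint8)
    p_ix = {prot: j for j, prot in enumerate(proteins)}
    for i, d in enumerate(diseases):
        for prot in protein_sets[d]:
            bits[i, p_ix[prot]] = 1
    matrix = DiseaseProteinMatrix(diseases, proteins, bits)

    # --- pathways -----------------------------------------------------
    rng = _rng(p, "pathways")
    genes = [f"G{i:03d}" for i in range(p.n_genes)]
    gene_sets: dict[str, set[str]] = {}
    for d in diseases:
        picks = rng.choice(p.n_genes, size=p.genes_per_disease, replace=False)
        gene_sets[d] = {genes[i] for i in picks}
    reactions: set[tuple[str, str]] = set()
    for u, v in sorted(planted, key=lambda e: (depths[e[0]], e)):
        src_pool = sorted(gene_sets[u])
        shared = rng.choice(
            len(src_pool), size=min(p.shared_genes_per_edge, len(src_pool)), replace=False
        )
        gene_sets[v] |= {src_pool[i] for i in shared}
        exclusive = sorted(gene_sets[u] - gene_sets[v])
        targets = sorted(gene_sets[v])
        # A fixed number of distinct reactions per planted edge keeps the
        # pathway evidence uniformly strong across the planted structure.
        combos = [
            (g_from, g_to)
            for g_from in exclusive
            for g_to in targets
            if g_from != g_to
        ]
        n_pick = min(p.reactions_per_edge, len(combos))
        if n_pick:
            picks = rng.choice(len(combos), size=n_pick, replace=False)
            reactions.update(combos[i] for i in picks)
        for _ in range(rng.poisson(p.reverse_reaction_rate)):
            rev_exclusive = sorted(gene_sets[v] - gene_sets[u])
            rev_targets = sorted(gene_sets[u])
            if rev_exclusive and rev_targets:
                g_from = rev_exclusive[rng.integers(len(rev_exclusive))]
                g_to = rev_targets[rng.integers(len(rev_targets))]
                if g_from != g_to:
                    reactions.add((g_from, g_to))
    for _ in range(p.noise_reactions):
        g_from, g_to = (genes[i] for i in rng.integers(p.n_genes, size=2))
        if g_from != g_to:
            reactions.add((g_from, g_to))
    pathways = PathwayData(gene_sets, reactions)

    # --- clinical history --------------------------------------------
    rng = _rng(p, "clinical")
    parent_ix = {
        d: [diseases.index(u) for u in sorted(preds[d])] for d in diseases
    }
    present = np.zeros((p.n_patients, p.n_diseases), dtype=np.uint8)
    d_index = {d: i for i, d in enumerate(diseases)}
    for d in order:
        i = d_index[d]
        p_base = p.base_prevalence * p.prevalence_decay ** depths[d]
        p_cond = min(p.rr_effect * p_base, 0.8)
        if parent_ix[d]:
            has_parent = present[:, parent_ix[d]].any(axis=1)
            prob = np.where(has_parent, p_cond, p_base)
        else:
            prob = np.full(p.n_patients, p_base)
        present[:, i] = rng.random(p.n_patients) < prob
    p32 = present.astype(np.int32)
    counts = p32.T @ p32
    n_single = {d: int(counts[i, i]) for d, i in d_index.items()}
    n_pair = {
        (diseases[i], diseases[j]): int(counts[i, j])
        for i in range(p.n_diseases)
        for j in range(i + 1, p.n_diseases)
        if counts[i, j] > 0
    }
    comorbidity = ComorbidityTable(p.n_patients, n_single, n_pair)

    # --- text ---------------------------------------------------------
    rng = _rng(p, "text")
    causal_terms = sorted(t for t, a in p.terms.items() if a >= 1.0)
    all_terms = sorted(p.terms)
    records: list[tuple[str, str, str, str, int]] = []
    doc_counter = 0

    def emit(src: str, dst: str, n_docs: int, vocabulary: list[str]) -> None:
        nonlocal doc_counter
        for _ in range(n_docs):
            term = vocabulary[rng.integers(len(vocabulary))]
            clauses = 1 + rng.poisson(max(p.clause_rate - 1.0, 0.0))
            records.append((term, src, dst, f"doc{doc_counter:06d}", int(clauses)))
            doc_counter += 1

    for u, v in sorted(planted):
        n_fwd = 1 + rng.poisson(p.docs_per_edge - 1.0)
        if p.text_symmetric:
            n_rev = 1 + rng.poisson(p.docs_per_edge - 1.0)
        else:
            n_rev = rng.poisson(p.reverse_doc_rate)
        emit(u, v, int(n_fwd), causal_terms)
        emit(v, u, int(n_rev), causal_terms)
    planted_set = set(planted)
    for _ in range(p.noise_text_pairs):
        i, j = rng.integers(p.n_diseases, size=2)
        if i == j or (diseases[i], diseases[j]) in planted_set:
            continue
        emit(diseases[i], diseases[j], 1, all_terms)
    text = TextEvidence(records)
    alphas = TermStrengthTable(dict(p.terms))

    return SyntheticWorld(
        params=p,
        diseases=diseases,
        planted=sorted(planted),
        depths=depths,
        matrix=matrix,
        pathways=pathways,
        comorbidity=comorbidity,
        text=text,
        alphas=alphas,
    )


def build_all_layers(world: SyntheticWorld) -> list[tuple[str, ProgressionNetwork]]:
    """Run the four builders on a world's raw evidence."""
    p = world.params
    return [
        ("ADN", build_adn(world.matrix, p.knn_k)),
        ("pDPN", build_pdpn(world.pathways)),
        ("cDPN", build_cdpn(world.comorbidity)),
        ("tDPN", build_tdpn(world.text, world.alphas)),
    ]


# ---------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------


def enumerate_loop_free_paths(
    g: DistanceGraph,
    s: str,
    t: str,
    max_hops: int | None = None,
) -> list[tuple[tuple[str, ...], float]]:
    """Exhaustive loop-free s -> t enumeration (test oracle).

    Guarded: requires <= 14 nodes unless an explicit ``max_hops`` bound
    is given.  Sorted by total distance, then hop count, then the
    lexicographic disease sequence — the same tie-break the search uses.
    """
    if max_hops is None:
        if len(g.nodes) > 14:
            raise ValueError("graph too large for exhaustive enumeration")
        max_hops = len(g.nodes) - 1
    if s == t:
        raise ValueError("source and target must differ")
    results: list[tuple[tuple[str, ...], float]] = []

    def dfs(path: list[str], dist: float) -> None:
        node = path[-1]
        if node == t:
            results.append((tuple(path), dist))
            return
        if len(path) > max_hops:
            return
        for v, d in g.successors(node):
            if v not in path:
                path.append(v)
                dfs(path, dist + d)
                path.pop()

    dfs([s], 0.0)
    results.sort(key=lambda r: (r[1], len(r[0]), r[0]))
    return results


# ---------------------------------------------------------------------
# Fixture catalogue
# ---------------------------------------------------------------------


def _fixture_diamond() -> dict:
    net = ProgressionNetwork()
    net.add_edge("s", "a", 0.9, {"cDPN"})
    net.add_edge("a", "t", 0.9, {"cDPN"})
    net.add_edge("s", "b", 0.7, {"cDPN"})
    net.add_edge("b", "t", 0.7, {"cDPN"})
    return {
        "network": net,
        "source": "s",
        "target": "t",
        "expected_paths": [("s", "a", "t"), ("s", "b", "t")],
    }


def _fixture_three_path() -> dict:
    net = ProgressionNetwork()
    for mid, w in (("a", 0.75), ("b", 0.65), ("c", 0.55)):
        net.add_edge("s", mid, w, {"cDPN"})
        net.add_edge(mid, "t", w, {"cDPN"})
    return {
        "network": net,
        "source": "s",
        "target": "t",
        "expected_paths": [("s", "a", "t"), ("s", "b", "t"), ("s", "c", "t")],
    }


def _fixture_tie_break() -> dict:
    net = ProgressionNetwork()
    for mid in ("a", "b"):
        net.add_edge("s", mid, 0.8, {"tDPN"})
        net.add_edge(mid, "t", 0.8, {"tDPN"})
    return {
        "network": net,
        "source": "s",
        "target": "t",
        "expected_paths": [("s", "a", "t"), ("s", "b", "t")],
    }


def _fixture_zero_distance() -> dict:
    # Contains a weight-1.0 (zero-distance) arc and a zero-cost 2-cycle.
    net = ProgressionNetwork()
    net.add_edge("s", "a", 1.0, {"pDPN"})
    net.add_edge("a", "s", 1.0, {"pDPN"})
    net.add_edge("a", "t", 0.5, {"pDPN"})
    net.add_edge("s", "t", 0.4, {"pDPN"})
    return {
        "network": net,
        "source": "s",
        "target": "t",
        "expected_paths": [("s", "a", "t"), ("s", "t")],
    }


def _fixture_colitis_toy() -> dict:
    """Toy replica of a colitis -> respiratory-insufficiency search.

    Five loop-free routes exist, three of length 4 sharing the
    polyuria -> hyponatremia -> respiratory-insufficiency tail and two
    of length 6 through oliguria.
    """
    w = {
        ("Colitis", "Acute_Kidney_Injury"): 0.80,
        ("Acute_Kidney_Injury", "Polyuria"): 0.80,
        ("Colitis", "Diabetes_Insipidus"): 0.75,
        ("Diabetes_Insipidus", "Polyuria"): 0.80,
        ("Colitis", "Polydipsia"): 0.70,
        ("Polydipsia", "Polyuria"): 0.75,
        ("Polyuria", "Hyponatremia"): 0.90,
        ("Hyponatremia", "Respiratory_Insufficiency"): 0.90,
        ("Acute_Kidney_Injury", "Oliguria"): 0.60,
        ("Oliguria", "Diabetes_Insipidus"): 0.60,
        ("Colitis", "Renal_Colic"): 0.55,
        ("Renal_Colic", "Oliguria"): 0.60,
    }
    net = ProgressionNetwork()
    for (u, v), weight in w.items():
        net.add_edge(u, v, weight, {"cDPN"})
    expected = [
        ("Colitis", "Acute_Kidney_Injury", "Polyuria", "Hyponatremia",
         "Respiratory_Insufficiency"),
        ("Colitis", "Diabetes_Insipidus", "Polyuria", "Hyponatremia",
         "Respiratory_Insufficiency"),
        ("Colitis", "Polydipsia", "Polyuria", "Hyponatremia",
         "Respiratory_Insufficiency"),
        ("Colitis", "Acute_Kidney_Injury", "Oliguria", "Diabetes_Insipidus",
         "Polyuria", "Hyponatremia", "Respiratory_Insufficiency"),
        ("Colitis", "Renal_Colic", "Oliguria", "Diabetes_Insipidus",
         "Polyuria", "Hyponatremia", "Respiratory_Insufficiency"),
    ]
    return {
        "network": net,
        "source": "Colitis",
        "target": "Respiratory_Insufficiency",
        "expected_paths": expected,
    }


FIXTURE_CATALOGUE = {
    "diamond": _fixture_diamond,
    "three-path": _fixture_three_path,
    "colitis-toy": _fixture_colitis_toy,
    "tie-break": _fixture_tie_break,
    "zero-distance": _fixture_zero_distance,
}


def make_fixture(name: str, outdir: str | Path | None = None) -> dict:
    """Build a catalogue fixture; optionally write its TSVs.

    Returns a dict with keys ``network``, ``source``, ``target`` and
    ``expected_paths`` (the loop-free source-target paths in the order
    the search must return them).
    """
    try:
        fixture = FIXTURE_CATALOGUE[name]()
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; catalogue: {sorted(FIXTURE_CATALOGUE)}"
        ) from None
    if outdir is not None:
        from .chainsearch import ScoreParams, k_shortest_chains, progression_score
        from .integrator import to_distance_graph
        from .netcore import write_chains_tsv, write_edge_list

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_edge_list(fixture["network"], outdir / "edges.tsv")
        g = to_distance_graph(fixture["network"])
        chains = k_shortest_chains(
            g, fixture["source"], fixture["target"], k=len(fixture["expected_paths"])
        )
        rows = []
        for rank, chain in enumerate(chains, start=1):
            progression_score(chain, ScoreParams())
            rows.append(
                {
                    "rank": rank,
                    "source": fixture["source"],
                    "target": fixture["target"],
                    "chain": "|".join(chain.diseases),
                    "length_l": chain.length,
                    "sum_weights": repr(chain.sum_weights),
                    "progression_score": repr(chain.score),
                }
            )
        write_chains_tsv(rows, outdir / "expected_chains.tsv")
    return fixture
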