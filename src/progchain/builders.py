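"""Builders for the four evidence-layer disease networks.

Each builder turns one kind of raw evidence into a directed, weighted
network over diseases:

* **ADN** (association disease network) — cosine similarity of the
  diseases' protein-association bit vectors, sparsified with k-nearest
  neighbours and emitted bidirected (association has no direction).
* **pDPN** (pathway-based) — a flow count of directed gene reactions
  running from one disease's exclusive genes into the other's gene
  set; the dominant direction keeps weight ``max(flow_ij, flow_ji)``.
* **cDPN** (clinical-history-based) — relative risk RR(A,B) =
  p(B|A)/p(B|not A) from patient counts; the direction with the larger
  RR gets weight RRR = RR(A,B)/RR(B,A).
* **tDPN** (text-based) — per-term document-clause frequency
  DCF = df * log(cf + 1), scaled by a term-strength lexicon alpha_t and
  compared across the two orientations of a disease pair.

Raw pDPN/cDPN/tDPN weights are unbounded and are normalized to (0, 1]
by dividing by the per-network maximum.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .netcore import ProgressionNetwork, logger

__all__ = [
    "DiseaseProteinMatrix",
    "PathwayData",
    "ComorbidityTable",
    "TextEvidence",
    "TermStrengthTable",
    "cosine_weight",
    "build_adn",
    "flow",
    "pdpn_weight",
    "build_pdpn",
    "relative_risk",
    "cdpn_weight",
    "build_cdpn",
    "dcf",
    "tdpn_weight",
    "build_tdpn",
    "normalize_raw_network",
]


# ---------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------


@dataclass
class DiseaseProteinMatrix:
    """Binary disease-by-protein incidence matrix."""

    diseases: list[str]
    proteins: list[str]
    bits: np.ndarray  # shape (n_diseases, n_proteins), dtype uint8

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.shape != (len(self.diseases), len(self.proteins)):
            raise ValueError("bit matrix shape does not match index lists")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("incidence entries must be 0 or 1")
        empty = np.flatnonzero(self.bits.sum(axis=1) == 0)
        if empty.size:
            bad = [self.diseases[i] for i in empty]
            raise ValueError(f"diseases with no protein associations: {bad}")

    @classmethod
    def from_associations(
        cls, pairs: Iterable[tuple[str, str]]
    ) -> "DiseaseProteinMatrix":
        pairs = list(pairs)
        diseases = sorted({d for d, _ in pairs})
        proteins = sorted({p for _, p in pairs})
        d_ix = {d: i for i, d in enumerate(diseases)}
        p_ix = {p: j for j, p in enumerate(proteins)}
        bits = np.zeros((len(diseases), len(proteins)), dtype=np.uint8)
        for d, p in pairs:
            bits[d_ix[d], p_ix[p]] = 1
        return cls(diseases, proteins, bits)


@dataclass
class PathwayData:
    """Per-disease pathway gene sets plus directed gene-gene reactions."""

    gene_sets: dict[str, set[str]]
    reactions: set[tuple[str, str]]

    def __post_init__(self) -> None:
        for d, genes in self.gene_sets.items():
            if not genes:
                raise ValueError(f"empty gene set for disease {d!r}")
        for g, g2 in self.reactions:
            if g == g2:
                raise ValueError(f"self-reaction {g!r} -> {g!r}")


@dataclass
class ComorbidityTable:
    """Patient counts supporting relative-risk computation.

    ``n_pair`` is keyed by the lexicographically sorted disease pair.
    """

    n_total: int
    n_single: dict[str, int]
    n_pair: dict[tuple[str, str], int]

    def __post_init__(self) -> None:
        if self.n_total < 0:
            raise ValueError("n_total must be non-negative")
        for d, n in self.n_single.items():
            if not 0 <= n <= self.n_total:
                raise ValueError(f"count for {d!r} outside [0, n_total]")
        normalized = {}
        for (a, b), n in self.n_pair.items():
            if a == b:
                raise ValueError(f"pair count for identical diseases {a!r}")
            key = (a, b) if a < b else (b, a)
            if key in normalized:
                raise ValueError(f"duplicate pair {key}")
            if n < 0 or n > min(self.n_single.get(a, 0), self.n_single.get(b, 0)):
                raise ValueError(
                    f"pair count {n} for {key} exceeds a single-disease count"
                )
            normalized[key] = n
        self.n_pair = normalized

    def pair_count(self, a: str, b: str) -> int:
        key = (a, b) if a < b else (b, a)
        return self.n_pair.get(key, 0)


@dataclass
class TextEvidence:
    """Clause-level literature records of directed disease mentions.

    Each record: (term, source disease, target disease, document id,
    clause count within that document).
    """

    records: list[tuple[str, str, str, str, int]]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str, str]] = set()
        for term, src, dst, doc, cc in self.records:
            if cc < 1:
                raise ValueError(
                    f"clause_count must be >= 1 (term {term!r}, doc {doc!r})"
                )
            key = (term, src, dst, doc)
            if key in seen:
                raise ValueError(f"duplicate (term, pair, document) record {key}")
            seen.add(key)

    def ordered_pairs(self) -> set[tuple[str, str]]:
        return {(src, dst) for _, src, dst, _, _ in self.records}

    def terms(self) -> set[str]:
        return {t for t, *_ in self.records}


@dataclass
class TermStrengthTable:
    """Lexicon mapping relation terms to strength alpha_t > 0."""

    strength: dict[str, float]

    def __post_init__(self) -> None:
        for t, a in self.strength.items():
            if a <= 0:
                raise ValueError(f"alpha for term {t!r} must be > 0")

    def __getitem__(self, term: str) -> float:
        try:
            return self.strength[term]
        except KeyError:
            raise KeyError(f"term {term!r} missing from strength table") from None


# ---------------------------------------------------------------------
# ADN: protein-sharing association
# ---------------------------------------------------------------------


def cosine_weight(v_i: np.ndarray, v_j: np.ndarray) -> float:
    """Cosine similarity of two protein-association bit vectors."""
    v_i = np.asarray(v_i, dtype=float)
    v_j = np.asarray(v_j, dtype=float)
    if v_i.shape != v_j.shape:
        raise ValueError("bit vectors must have equal length")
    ni = math.sqrt(float(v_i @ v_i))
    nj = math.sqrt(float(v_j @ v_j))
    if ni == 0.0 or nj == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(v_i @ v_j) / (ni * nj)


def build_adn(m: DiseaseProteinMatrix, knn_k: int) -> ProgressionNetwork:
    """Build the bidirected association network with k-NN sparsification.

    A directed pair (i, j) survives iff j is among i's ``knn_k`` most
    similar neighbours or i is among j's (union rule; ties at the k-th
    similarity are all kept).  Surviving pairs are emitted in both
    directions with the cosine weight.
    """
    if knn_k < 1:
        raise ValueError("knn_k must be >= 1")
    bits = m.bits.astype(float)
    norms = np.linalg.norm(bits, axis=1)
    sim = (bits @ bits.T) / np.outer(norms, norms)
    np.fill_diagonal(sim, 0.0)
    # Clamp float error; cosine of binary vectors is within [0, 1].
    sim = np.clip(sim, 0.0, 1.0)

    n = len(m.diseases)
    keep: set[tuple[int, int]] = set()
    for i in range(n):
        row = sim[i]
        positive = np.flatnonzero(row > 0)
        if positive.size == 0:
            continue
        if positive.size > knn_k:
            # k-th largest positive similarity; keep every neighbour at
            # or above it so ties are retained.
            kth = np.sort(row[positive])[-knn_k]
            neighbours = positive[row[positive] >= kth]
        else:
            neighbours = positive
        for j in neighbours:
            keep.add((min(i, int(j)), max(i, int(j))))

    net = ProgressionNetwork()
    for d in m.diseases:
        net.add_node(d)
    for i, j in sorted(keep):
        w = float(sim[i, j])
        net.add_edge(m.diseases[i], m.diseases[j], w, {"ADN"})
        net.add_edge(m.diseases[j], m.diseases[i], w, {"ADN"})
    return net


# ---------------------------------------------------------------------
# pDPN: pathway flow
# ---------------------------------------------------------------------


def flow(p: PathwayData, d_i: str, d_j: str) -> tuple[int, int]:
    """Directed reaction counts between the exclusive genes of two diseases.

    The sharing block S is the intersection of the two gene sets;
    ``flow_ij`` counts reactions (g -> g') with g exclusive to ``d_i``
    (outside S) and g' in ``d_j``'s gene set, and symmetrically for
    ``flow_ji``.
    """
    for d in (d_i, d_j):
        if d not in p.gene_sets:
            raise KeyError(f"no gene set for disease {d!r}")
    gi, gj = p.gene_sets[d_i], p.gene_sets[d_j]
    shared = gi & gj
    flow_ij = sum(1 for g, g2 in p.reactions if g in gi - shared and g2 in gj)
    flow_ji = sum(1 for g, g2 in p.reactions if g in gj - shared and g2 in gi)
    return flow_ij, flow_ji


def pdpn_weight(flow_ij: int, flow_ji: int) -> tuple[float, float]:
    """Raw pathway weight: dominant-direction flow, ties suppressed."""
    if flow_ij < 0 or flow_ji < 0:
        raise ValueError("flow counts must be non-negative")
    if flow_ij > flow_ji:
        return float(flow_ij), 0.0
    if flow_ji > flow_ij:
        return 0.0, float(flow_ji)
    return 0.0, 0.0


def build_pdpn(p: PathwayData) -> ProgressionNetwork:
    """Pathway-based progression network over all diseases with gene sets."""
    diseases = sorted(p.gene_sets)
    raw: dict[tuple[str, str], float] = {}
    for a_ix, d_i in enumerate(diseases):
        for d_j in diseases[a_ix + 1 :]:
            f_ij, f_ji = flow(p, d_i, d_j)
            r_ij, r_ji = pdpn_weight(f_ij, f_ji)
            if r_ij > 0:
                raw[(d_i, d_j)] = r_ij
            if r_ji > 0:
                raw[(d_j, d_i)] = r_ji
    net = normalize_raw_network(raw, "pDPN")
    for d in diseases:
        net.add_node(d)
    return net


# ---------------------------------------------------------------------
# cDPN: clinical relative risk
# ---------------------------------------------------------------------


def relative_risk(t: ComorbidityTable, a: str, b: str) -> float:
    """RR(A, B) = p(B|A) / p(B|not A) from the four patient counts.

    Returns ``math.inf`` when p(B|not A) = 0 but p(B|A) > 0.
    """
    n_a = t.n_single.get(a)
    n_b = t.n_single.get(b)
    if n_a is None or n_b is None:
        raise KeyError(f"missing single-disease count for {a!r} or {b!r}")
    if n_a == 0 or n_a == t.n_total:
        raise ValueError(
            f"RR({a!r}, {b!r}) undefined: conditioning disease count is "
            f"{n_a} of {t.n_total}"
        )
    n_ab = t.pair_count(a, b)
    p_b_given_a = n_ab / n_a
    p_b_given_not_a = (n_b - n_ab) / (t.n_total - n_a)
    if p_b_given_not_a == 0.0:
        if p_b_given_a == 0.0:
            raise ValueError(f"RR({a!r}, {b!r}) undefined: 0/0")
        return math.inf
    return p_b_given_a / p_b_given_not_a


def cdpn_weight(rr_ij: float, rr_ji: float) -> tuple[float, float]:
    """Raw clinical weight: RRR of the dominant direction, ties suppressed."""
    if not (math.isfinite(rr_ij) and math.isfinite(rr_ji)):
        raise ValueError("relative risks must be finite (filter degenerate pairs)")
    if rr_ji <= 0 or rr_ij <= 0:
        raise ValueError("relative risks must be > 0 (filter degenerate pairs)")
    if rr_ij > rr_ji:
        return rr_ij / rr_ji, 0.0
    if rr_ji > rr_ij:
        return 0.0, rr_ji / rr_ij
    return 0.0, 0.0


def build_cdpn(
    t: ComorbidityTable,
    rrr_min: float = 1.05,
    min_pair_count: int = 50,
) -> ProgressionNetwork:
    """Clinical-history progression network from comorbidity counts.

    Only pairs with at least ``min_pair_count`` co-occurring patients
    and a dominant-direction RRR above ``rrr_min`` produce an edge; the
    two guards suppress directions that are indistinguishable from
    sampling noise.  Set ``rrr_min=1.0, min_pair_count=0`` for the
    unguarded definition.
    """
    diseases = sorted(t.n_single)
    raw: dict[tuple[str, str], float] = {}
    skipped = 0
    for a, b in sorted(t.n_pair):
        if t.pair_count(a, b) < min_pair_count:
            continue
        try:
            rr_ab = relative_risk(t, a, b)
            rr_ba = relative_risk(t, b, a)
            r_ab, r_ba = cdpn_weight(rr_ab, rr_ba)
        except (ValueError, KeyError):
            skipped += 1
            continue
        if r_ab > rrr_min:
            raw[(a, b)] = r_ab
        elif r_ba > rrr_min:
            raw[(b, a)] = r_ba
    if skipped:
        logger.info("cDPN: skipped %d pairs with degenerate relative risk", skipped)
    net = normalize_raw_network(raw, "cDPN")
    for d in diseases:
        net.add_node(d)
    return net


# ---------------------------------------------------------------------
# tDPN: literature evidence
# ---------------------------------------------------------------------


def dcf(df: int, cf: int, log_base: float | None = None) -> float:
    """Document-clause frequency df * log(cf + 1).

    ``log_base`` of None means the natural logarithm.
    """
    if df < 0 or cf < 0:
        raise ValueError("document and clause counts must be non-negative")
    if cf < df:
        raise ValueError(
            f"clause count {cf} < document count {df}: every counted "
            "document contributes at least one clause"
        )
    value = math.log(cf + 1)
    if log_base is not None:
        value /= math.log(log_base)
    return df * value


def _pair_strength(
    ev: TextEvidence,
    alphas: TermStrengthTable,
    i: str,
    j: str,
    log_base: float | None,
) -> float:
    """s_ij = sum over terms of alpha_t * DCF_t for the ordered pair."""
    per_term: dict[str, tuple[set[str], int]] = {}
    for term, src, dst, doc, cc in ev.records:
        if (src, dst) != (i, j):
            continue
        docs, clauses = per_term.get(term, (set(), 0))
        docs.add(doc)
        per_term[term] = (docs, clauses + cc)
    s = 0.0
    for term, (docs, clauses) in per_term.items():
        s += alphas[term] * dcf(len(docs), clauses, log_base)
    return s


def tdpn_weight(
    ev: TextEvidence,
    alphas: TermStrengthTable,
    i: str,
    j: str,
    log_base: float | None = None,
) -> tuple[float, float]:
    """Raw text weight: positive part of s_ij - s_ji (and its reverse)."""
    s_ij = _pair_strength(ev, alphas, i, j, log_base)
    s_ji = _pair_strength(ev, alphas, j, i, log_base)
    diff = s_ij - s_ji
    if diff > 0:
        return diff, 0.0
    if diff < 0:
        return 0.0, -diff
    return 0.0, 0.0


def build_tdpn(
    ev: TextEvidence,
    alphas: TermStrengthTable,
    log_base: float | None = None,
) -> ProgressionNetwork:
    """Text-based progression network from clause-level evidence."""
    for term in ev.terms():
        alphas[term]  # raises KeyError naming the term if absent
    pairs = {tuple(sorted(p)) for p in ev.ordered_pairs()}
    raw: dict[tuple[str, str], float] = {}
    for a, b in sorted(pairs):
        r_ab, r_ba = tdpn_weight(ev, alphas, a, b, log_base)
        if r_ab > 0:
            raw[(a, b)] = r_ab
        elif r_ba > 0:
            raw[(b, a)] = r_ba
    net = normalize_raw_network(raw, "tDPN")
    for src, dst in ev.ordered_pairs():
        net.add_node(src)
        net.add_node(dst)
    return net


# ---------------------------------------------------------------------
# Shared normalization
# ---------------------------------------------------------------------


def normalize_raw_network(
    raw: Mapping[tuple[str, str], float], tag: str
) -> ProgressionNetwork:
    """Scale raw weights into (0, 1] by the per-network maximum.

    Zero-weight entries are dropped; an all-zero input yields an empty
    network with a warning.
    """
    net = ProgressionNetwork()
    positive = {e: w for e, w in raw.items() if w > 0}
    if any(w < 0 for w in raw.values()):
        raise ValueError("raw weights must be non-negative")
    if not positive:
        logger.warning("%s: all raw weights are zero; emitting empty network", tag)
        return net
    w_max = max(positive.values())
    for (u, v), w in positive.items():
        net.add_edge(u, v, w / w_max, {tag})
    return net


# ---------------------------------------------------------------------
# Readers for the raw-evidence TSV dialects
# ---------------------------------------------------------------------


def _read_tsv(path: str | Path, expected_header: Sequence[str]):
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != list(expected_header):
            raise ValueError(
                f"{path}: expected header {list(expected_header)}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(expected_header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(expected_header)} columns"
                )
            yield lineno, row


def read_disease_protein_tsv(path: str | Path) -> DiseaseProteinMatrix:
    pairs = [(row[0], row[1]) for _, row in _read_tsv(path, ["disease_id", "protein_id"])]
    return DiseaseProteinMatrix.from_associations(pairs)


def read_pathway_tsvs(
    membership_path: str | Path, reactions_path: str | Path
) -> PathwayData:
    gene_sets: dict[str, set[str]] = {}
    for _, row in _read_tsv(membership_path, ["disease_id", "gene_id"]):
        gene_sets.setdefault(row[0], set()).add(row[1])
    reactions = {
        (row[0], row[1]) for _, row in _read_tsv(reactions_path, ["gene_from", "gene_to"])
    }
    return PathwayData(gene_sets, reactions)


def read_comorbidity_tsvs(
    totals_path: str | Path,
    singles_path: str | Path,
    pairs_path: str | Path,
) -> ComorbidityTable:
    totals = [int(row[0]) for _, row in _read_tsv(totals_path, ["n_total"])]
    if len(totals) != 1:
        raise ValueError(f"{totals_path}: expected exactly one total-count row")
    n_single = {
        row[0]: int(row[1]) for _, row in _read_tsv(singles_path, ["disease_id", "count"])
    }
    n_pair: dict[tuple[str, str], int] = {}
    for lineno, row in _read_tsv(pairs_path, ["disease_a", "disease_b", "count"]):
        a, b = row[0], row[1]
        if a >= b:
            raise ValueError(
                f"{pairs_path}:{lineno}: pair must be lexicographically sorted"
            )
        n_pair[(a, b)] = int(row[2])
    return ComorbidityTable(totals[0], n_single, n_pair)


def read_text_evidence_tsv(path: str | Path) -> TextEvidence:
    header = ["term", "source_disease", "target_disease", "document_id", "clause_count"]
    records = []
    for lineno, row in _read_tsv(path, header):
        cc = int(row[4])
        if cc < 1:
            raise ValueError(f"{path}:{lineno}: clause_count must be >= 1")
        records.append((row[0], row[1], row[2], row[3], cc))
    return TextEvidence(records)


def read_term_strength_tsv(path: str | Path) -> TermStrengthTable:
    strength = {
        row[0]: float(row[1]) for _, row in _read_tsv(path, ["term", "alpha"])
    }
    return TermStrengthTable(strength)
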