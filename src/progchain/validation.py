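"""Validation of progression chains against clinical comorbidity data.

A chain built *without* clinical-history evidence can be checked
against it: for every consecutive disease pair (d_i -> d_j) in a chain
the ratio of relative risks RRR(d_i, d_j) = RR(d_i, d_j) / RR(d_j, d_i)
is computed from patient counts.  RRR > 1 supports the chain's
direction; a chain is supported when the mean of its defined per-arc
RRRs exceeds 1.  Pairs without evaluable clinical records are skipped,
not counted as failures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .builders import ComorbidityTable, relative_risk
from .chainsearch import ProgressionChain
from .integrator import IntegrationConfig, integrate
from .netcore import ProgressionNetwork, logger

__all__ = ["ValidationReport", "rrr", "validate_chains", "leave_source_out"]


@dataclass(frozen=True)
class ValidationReport:
    """Counts and fractions of clinically supported relations and chains."""

    n_relations: int
    n_relations_rrr_gt1: int
    fraction_relations: float
    n_chains: int
    n_chains_avg_rrr_gt1: int
    fraction_chains: float
    rrr_values: tuple[float, ...]
    skipped: int


def rrr(t: ComorbidityTable, a: str, b: str) -> float | None:
    """RRR(a, b) = RR(a, b) / RR(b, a), or None when undefined.

    Undefined cases: a disease missing from the table, a degenerate
    conditioning count, an infinite RR, or RR(b, a) = 0.
    """
    try:
        rr_ab = relative_risk(t, a, b)
        rr_ba = relative_risk(t, b, a)
    except (KeyError, ValueError):
        return None
    if not (math.isfinite(rr_ab) and math.isfinite(rr_ba)) or rr_ba == 0.0:
        return None
    return rr_ab / rr_ba


def validate_chains(
    chains: list[ProgressionChain], t: ComorbidityTable
) -> ValidationReport:
    """Score every chain arc by RRR direction agreement.

    A relation is correct iff RRR > 1 (strict); a chain is correct iff
    the arithmetic mean of its defined per-relation RRRs is > 1.
    Chains with no evaluable relation are excluded from the chain
    denominator.
    """
    if not chains:
        raise ValueError("no chains to validate")
    rrr_values: list[float] = []
    skipped = 0
    n_chains = 0
    n_chains_ok = 0
    for chain in chains:
        per_chain: list[float] = []
        for a, b in zip(chain.diseases, chain.diseases[1:]):
            value = rrr(t, a, b)
            if value is None:
                skipped += 1
                continue
            per_chain.append(value)
            rrr_values.append(value)
        if per_chain:
            n_chains += 1
            if sum(per_chain) / len(per_chain) > 1.0:
                n_chains_ok += 1
    if not rrr_values:
        raise ValueError("no evaluable prior-posterior relation in any chain")
    n_ok = sum(1 for v in rrr_values if v > 1.0)
    return ValidationReport(
        n_relations=len(rrr_values),
        n_relations_rrr_gt1=n_ok,
        fraction_relations=n_ok / len(rrr_values),
        n_chains=n_chains,
        n_chains_avg_rrr_gt1=n_chains_ok,
        fraction_chains=n_chains_ok / n_chains if n_chains else 0.0,
        rrr_values=tuple(rrr_values),
        skipped=skipped,
    )


def leave_source_out(
    nets: list[tuple[str, ProgressionNetwork]],
    cfg: IntegrationConfig | None = None,
    excluded: str = "cDPN",
) -> ProgressionNetwork:
    """Integrate all layers except ``excluded`` (e.g. leave-clinical-out)."""
    tags = [tag for tag, _ in nets]
    if excluded not in tags:
        raise ValueError(f"tag {excluded!r} not among supplied networks {tags}")
    remaining = [(tag, net) for tag, net in nets if tag != excluded]
    if not remaining:
        raise ValueError("excluding the tag would leave no networks")
    logger.info("integrating %d layers, excluding %s", len(remaining), excluded)
    return integrate(remaining, cfg)
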