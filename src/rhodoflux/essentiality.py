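"""Single reaction/gene deletion screens and four-way reaction classification.

A reaction is essential when forcing its flux to zero drops the optimal
growth rate below the growth threshold ("production of no biomass"); a gene
is essential when knocking it out disables, through the boolean GPR rules,
a set of reactions whose collective loss abolishes growth.  Reactions are
further partitioned for a given condition into

    essential            knockout abolishes growth
    active_nonessential  can carry flux at the growth optimum, not essential
    condition_inactive   no flux possible here, but unblocked in the fully
                         open system (needed only under other conditions)
    blocked              cannot carry flux under any condition

using flux variability at the fixed optimum and in the fully open system.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .conditions import GROWTH_THRESHOLD, Medium
from .lp_engine import ZERO_FLUX_TOL, fba, find_blocked, fva
from .model_core import MetabolicModel


@dataclass
class DeletionResult:
    kind: str  # reaction | gene
    entity: str
    wildtype_growth: float
    knockout_growth: float
    essential: bool


def _knockout_growth(model, medium, objective_id, knocked_reactions):
    dist = fba(model, medium, objective_id, knocked=knocked_reactions)
    return dist.objective_value if dist.optimal else 0.0


def single_reaction_deletion(
    model: MetabolicModel, medium: Medium | None = None,
    objective_id: str | None = None,
) -> list[DeletionResult]:
    """Sequentially zero each reaction's flux and recompute optimal growth."""
    wt = fba(model, medium, objective_id)
    if not wt.optimal:
        raise RuntimeError(f"wild-type FBA is {wt.status}")
    results = []
    for rid in model.reactions:
        g = _knockout_growth(model, medium, objective_id, (rid,))
        results.append(
            DeletionResult("reaction", rid, wt.objective_value, g,
                           g <= GROWTH_THRESHOLD)
        )
    return results


def single_gene_deletion(
    model: MetabolicModel, medium: Medium | None = None,
    objective_id: str | None = None,
) -> list[DeletionResult]:
    """Knock out each gene; reactions whose GPR evaluates inactive get
    bounds (0, 0).  Genes with no associated reactions are trivially
    non-essential."""
    wt = fba(model, medium, objective_id)
    if not wt.optimal:
        raise RuntimeError(f"wild-type FBA is {wt.status}")
    results = []
    for gene in sorted(model.genes):
        knocked = frozenset([gene])
        disabled = [
            rid for rid in model.reactions_for_gene(gene)
            if not model.reactions[rid].gpr.evaluate(knocked)
        ]
        if disabled:
            g = _knockout_growth(model, medium, objective_id, disabled)
        else:
            g = wt.objective_value  # isozymes cover every associated reaction
        results.append(
            DeletionResult("gene", gene, wt.objective_value, g,
                           g <= GROWTH_THRESHOLD)
        )
    return results


def classify_reactions(
    model: MetabolicModel, medium: Medium | None = None,
    objective_id: str | None = None,
) -> dict[str, str]:
    """Map reaction id -> {essential, active_nonessential, condition_inactive,
    blocked} for one growth condition."""
    deletions = {r.entity: r for r in single_reaction_deletion(model, medium, objective_id)}
    at_optimum = fva(model, medium, objective_id)
    blocked_open = find_blocked(model, "open")
    classes = {}
    for rid in model.reactions:
        if deletions[rid].essential:
            classes[rid] = "essential"
            continue
        lo, hi = at_optimum.ranges[rid]
        if abs(lo) > ZERO_FLUX_TOL or abs(hi) > ZERO_FLUX_TOL:
            classes[rid] = "active_nonessential"
        elif rid in blocked_open:
            classes[rid] = "blocked"
        else:
            classes[rid] = "condition_inactive"
    return classes


def deletion_table(results: list[DeletionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"kind": r.kind, "entity": r.entity,
             "wildtype_growth": r.wildtype_growth,
             "knockout_growth": r.knockout_growth, "essential": r.essential}
            for r in results
        ]
    )


def classification_summary(classes: dict[str, str]) -> dict[str, int]:
    counts = {"essential": 0, "active_nonessential": 0,
              "condition_inactive": 0, "blocked": 0}
    for c in classes.values():
        counts[c] += 1
    return counts
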