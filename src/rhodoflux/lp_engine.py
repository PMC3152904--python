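"""Solver-agnostic LP core: FBA, FVA, blocked reactions, balanced cycles.

Flux balance analysis solves

    max  c.v        (c selects the objective reaction, usually biomass)
    s.t. S.v = 0    (steady-state mass balance)
         vmin <= v <= vmax

with HiGHS through :func:`scipy.optimize.linprog`.  Flux variability
analysis fixes the objective at its optimum Z (within a small relative
slack band, since a strict equality is numerically brittle) and then
minimizes/maximizes each reaction flux in turn.

Numerical conventions: feasibility tolerance 1e-9; fluxes with magnitude
below ``ZERO_FLUX_TOL`` = 1e-6 mmol/gDW/h are treated as zero when
classifying blocked reactions or cycle members.  The 1e-6 threshold is the
sensitivity knob behind any active/inactive partition reported downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import linprog

from .model_core import MetabolicModel, build_matrix

ZERO_FLUX_TOL = 1e-6
FEASIBILITY_TOL = 1e-9
OBJECTIVE_SLACK = 1e-6  # relative band when fixing Z in FVA / enumeration


@dataclass
class FluxDistribution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float | None
    fluxes: dict[str, float] = field(default_factory=dict)
    objective_id: str | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("reaction\tflux\n")
            for rid, v in self.fluxes.items():
                fh.write(f"{rid}\t{v:.10g}\n")


@dataclass
class FvaResult:
    objective_fixed_at: float | None
    ranges: dict[str, tuple[float, float]]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("reaction\tmin\tmax\n")
            for rid, (lo, hi) in self.ranges.items():
                fh.write(f"{rid}\t{lo:.10g}\t{hi:.10g}\n")


# ---------------------------------------------------------------------------
# LP assembly
# ---------------------------------------------------------------------------

def _medium_overrides(medium) -> dict[str, tuple[float, float]]:
    if medium is None:
        return {}
    if hasattr(medium, "bounds"):  # conditions.Medium
        return dict(medium.bounds)
    return dict(medium)


def build_lp(model: MetabolicModel, medium=None, knocked=()):
    """Assemble (S, reaction ids, lb, ub) with medium overrides applied on
    top of the model's default bounds; ``knocked`` reactions get (0, 0)."""
    S, _met_ids, rxn_ids = build_matrix(model)
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    index = {r: i for i, r in enumerate(rxn_ids)}
    for rid, (lo, hi) in _medium_overrides(medium).items():
        if rid not in index:
            raise KeyError(f"medium references unknown reaction {rid!r}")
        lb[index[rid]], ub[index[rid]] = lo, hi
    for rid in knocked:
        lb[index[rid]] = ub[index[rid]] = 0.0
    return S, rxn_ids, lb, ub


_STATUS = {0: "optimal", 1: "iteration-limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _solve(c, S, lb, ub):
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    return res, _STATUS.get(res.status, "numerical")


def fba(
    model: MetabolicModel,
    medium=None,
    objective_id: str | None = None,
    sense: str = "max",
    knocked=(),
) -> FluxDistribution:
    """Flux balance analysis.  Returns one solver-chosen optimal vertex;
    degenerate alternate optima are the enumeration module's concern."""
    objective_id = objective_id or model.objective_reaction_id
    if objective_id is None or objective_id not in model.reactions:
        raise KeyError(f"objective reaction {objective_id!r} not in model")
    S, rxn_ids, lb, ub = build_lp(model, medium, knocked)
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(objective_id)] = -1.0 if sense == "max" else 1.0
    res, status = _solve(c, S, lb, ub)
    if status != "optimal":
        return FluxDistribution(status, None, {}, objective_id)
    fluxes = dict(zip(rxn_ids, res.x))
    return FluxDistribution("optimal", fluxes[objective_id], fluxes, objective_id)


def _fva_core(S, rxn_ids, lb, ub, subset_idx):
    """Min/max each flux in ``subset_idx`` under the current bounds."""
    ranges = {}
    n = len(rxn_ids)
    for j in subset_idx:
        c = np.zeros(n)
        c[j] = 1.0
        lo_res, lo_status = _solve(c, S, lb, ub)
        c[j] = -1.0
        hi_res, hi_status = _solve(c, S, lb, ub)
        if lo_status != "optimal" or hi_status != "optimal":
            raise RuntimeError(
                f"FVA subproblem for {rxn_ids[j]!r} ended {lo_status}/{hi_status}; "
                "check objective-fixing tolerance"
            )
        lo = float(lo_res.x[j])
        hi = float(hi_res.x[j])
        if lo > hi:  # solver jitter on a point range
            lo = hi = 0.5 * (lo + hi)
        ranges[rxn_ids[j]] = (lo, hi)
    return ranges


def fva(
    model: MetabolicModel,
    medium=None,
    objective_id: str | None = None,
    reactions=None,
    fraction_of_optimum: float = 1.0,
) -> FvaResult:
    """Flux variability analysis with the objective fixed at the FBA optimum.

    The objective flux is constrained to the band
    ``[Z*f - slack, Z*f + slack]`` with relative slack 1e-6, ``f`` the
    fraction of optimum (1.0 reproduces the strict fixed-Z definition).
    """
    objective_id = objective_id or model.objective_reaction_id
    wt = fba(model, medium, objective_id)
    if not wt.optimal:
        raise RuntimeError(f"FBA under the given medium is {wt.status}")
    Z = wt.objective_value
    S, rxn_ids, lb, ub = build_lp(model, medium)
    obj_j = rxn_ids.index(objective_id)
    target = Z * fraction_of_optimum
    slack = OBJECTIVE_SLACK * max(1.0, abs(target))
    lb[obj_j] = max(lb[obj_j], target - slack)
    ub[obj_j] = min(ub[obj_j], target + slack)
    subset = reactions if reactions is not None else rxn_ids
    subset_idx = [rxn_ids.index(r) for r in subset]
    ranges = _fva_core(S, rxn_ids, lb, ub, subset_idx)
    return FvaResult(Z, ranges)


def find_blocked(model: MetabolicModel, medium="open") -> set[str]:
    """Reactions unable to carry any flux, without fixing an objective.

    ``medium="open"`` reproduces the fully open system: every exchange may
    run both ways (-1000, 1000) and demands/sinks are fully relaxed.
    """
    if medium == "open":
        medium = {}
        for rid in model.boundary_reactions():
            rxn = model.reactions[rid]
            if rxn.category == "demand":
                medium[rid] = (0.0, 1000.0)
            else:
                medium[rid] = (-1000.0, 1000.0)
    S, rxn_ids, lb, ub = build_lp(model, medium)
    ranges = _fva_core(S, rxn_ids, lb, ub, range(len(rxn_ids)))
    return {
        rid for rid, (lo, hi) in ranges.items()
        if abs(lo) <= ZERO_FLUX_TOL and abs(hi) <= ZERO_FLUX_TOL
    }


def detect_sbcs(model: MetabolicModel) -> list[set[str]]:
    """Stoichiometrically balanced cycles: groups of reactions that can carry
    flux with every exchange/demand/sink closed.

    Member reactions are grouped into connected components through shared
    metabolites.  Detection only — resolving a cycle by directionality
    curation is the modeler's job.
    """
    closed = {rid: (0.0, 0.0) for rid in model.boundary_reactions()}
    # relax forced fluxes (e.g. fixed ATP maintenance) so the closed system
    # stays feasible at v = 0
    for rid, rxn in model.reactions.items():
        if rid in closed:
            continue
        if rxn.lower_bound > 0 or rxn.upper_bound < 0:
            closed[rid] = (min(rxn.lower_bound, 0.0), max(rxn.upper_bound, 0.0))
    S, rxn_ids, lb, ub = build_lp(model, closed)
    ranges = _fva_core(S, rxn_ids, lb, ub, range(len(rxn_ids)))
    members = [
        rid for rid, (lo, hi) in ranges.items()
        if abs(lo) > ZERO_FLUX_TOL or abs(hi) > ZERO_FLUX_TOL
    ]
    graph = nx.Graph()
    graph.add_nodes_from(members)
    member_set = set(members)
    met_to_rxns: dict[str, list[str]] = {}
    for rid in members:
        for mid in model.reactions[rid].stoichiometry:
            met_to_rxns.setdefault(mid, []).append(rid)
    for rxns in met_to_rxns.values():
        for a, b in zip(rxns, rxns[1:]):
            if a in member_set and b in member_set:
                graph.add_edge(a, b)
    return [set(c) for c in nx.connected_components(graph)]


def check_flux_distribution(model: MetabolicModel, dist: FluxDistribution,
                            medium=None, knocked=()) -> float:
    """Max |S.v| of a solution — the steady-state residual (0 when valid)."""
    S, rxn_ids, _lb, _ub = build_lp(model, medium, knocked)
    v = np.array([dist.fluxes[r] for r in rxn_ids])
    return float(np.max(np.abs(S @ v))) if len(v) else 0.0
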