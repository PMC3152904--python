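"""Growth-condition handling: media, condition simulation, source screens.

A :class:`Medium` is a named set of exchange-bound overrides applied on top
of the model's default bounds at LP-build time — the model object itself is
never mutated, so applying then dropping a medium trivially restores the
baseline.  Media serialize to/from YAML with one ``exchange-id: [lower,
upper]`` entry per line.

The substrate screen follows the single-source-replacement protocol: the
baseline minimal medium supplies exactly one source of the element under
test; that source is closed, the candidate's uptake opened (adding a
temporary reversible sink when the candidate has no boundary reaction), the
growth LP solved, and the model restored bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import yaml

from ._formula import element_count
from .lp_engine import FluxDistribution, fba
from .model_core import MetabolicModel, add_boundary_reaction

GROWTH_THRESHOLD = 1e-6  # 1/h; separates growth from numerical noise
DEFAULT_UPTAKE = 10.0  # mmol/gDW/h opened for screened candidate sources


@dataclass
class Medium:
    name: str = "medium"
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    notes: str = ""

    def updated(self, extra: dict[str, tuple[float, float]], name=None) -> "Medium":
        merged = dict(self.bounds)
        merged.update(extra)
        return Medium(name or self.name, merged, self.notes)

    def without(self, *rids: str) -> "Medium":
        return Medium(self.name, {k: v for k, v in self.bounds.items() if k not in rids}, self.notes)

    def to_yaml(self, path) -> None:
        data = {
            "name": self.name,
            "notes": self.notes,
            "bounds": {rid: [float(lo), float(hi)] for rid, (lo, hi) in self.bounds.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @staticmethod
    def from_yaml(path) -> "Medium":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return Medium(
            name=data.get("name", "medium"),
            bounds={rid: (float(lo), float(hi)) for rid, (lo, hi) in data.get("bounds", {}).items()},
            notes=data.get("notes", ""),
        )


@dataclass
class GrowthPhenotype:
    condition: str
    growth_rate: float
    grows: bool
    status: str = "optimal"


def apply_medium(model: MetabolicModel, medium: Medium) -> dict[str, tuple[float, float]]:
    """Mutate the model's bounds in place; returns the baseline bounds needed
    by :func:`revert_medium` to restore the model exactly."""
    baseline = {}
    for rid, (lo, hi) in medium.bounds.items():
        rxn = model.reactions[rid]
        baseline[rid] = (rxn.lower_bound, rxn.upper_bound)
        rxn.lower_bound, rxn.upper_bound = lo, hi
    return baseline


def revert_medium(model: MetabolicModel, baseline: dict[str, tuple[float, float]]) -> None:
    for rid, (lo, hi) in baseline.items():
        model.reactions[rid].lower_bound, model.reactions[rid].upper_bound = lo, hi


def simulate_condition(
    model: MetabolicModel, medium: Medium, objective_id: str | None = None
) -> tuple[GrowthPhenotype, FluxDistribution]:
    """FBA under one growth condition.  An infeasible LP is a biological
    no-growth call (rate 0), not an exception."""
    dist = fba(model, medium, objective_id)
    if dist.optimal:
        rate = float(dist.objective_value)
        return GrowthPhenotype(medium.name, rate, bool(rate > GROWTH_THRESHOLD)), dist
    return GrowthPhenotype(medium.name, 0.0, False, status=dist.status), dist


def substrate_screen(
    model: MetabolicModel,
    baseline: Medium,
    element: str,
    candidates: list[str] | None = None,
    source_exchange: str | None = None,
    objective_id: str | None = None,
    uptake: float = DEFAULT_UPTAKE,
) -> pd.DataFrame:
    """Screen alternative sources of one element (C, N, P or S).

    ``source_exchange`` is the baseline exchange supplying the element; if
    omitted it is taken as the unique exchange in the medium with an open
    lower bound whose metabolite contains the element.  Candidates default
    to every metabolite carrying >= 1 atom of the element that has, or can
    be given, a boundary reaction.  Returns a table with columns
    (candidate, growth_rate, grows, note).
    """
    if source_exchange is None:
        hits = []
        for rid, (lo, _hi) in baseline.bounds.items():
            if lo >= 0:
                continue
            rxn = model.reactions[rid]
            if rxn.category != "exchange":
                continue
            (mid,) = rxn.stoichiometry
            formula = model.metabolites[mid].formula
            if formula and element_count(formula, element) > 0:
                hits.append((rid, lo))
        # freely exchanged components (bound at the -1000 box) such as CO2 or
        # water are not "the" source; measured finite uptakes take precedence
        measured = [rid for rid, lo in hits if lo > -1000.0]
        if len(measured) == 1:
            source_exchange = measured[0]
        elif len(hits) == 1:
            source_exchange = hits[0][0]
        else:
            raise ValueError(
                f"baseline medium must have exactly one open {element} source, "
                f"found {[rid for rid, _ in hits]}"
            )

    if candidates is None:
        candidates = [
            m.id for m in model.metabolites.values()
            if m.formula and element_count(m.formula, element) > 0
            and m.compartment == model.metabolites[
                next(iter(model.reactions[source_exchange].stoichiometry))
            ].compartment
        ]

    before = model.to_dict()
    rows = []
    for cand in sorted(candidates):
        if cand not in model.metabolites:
            rows.append({"candidate": cand, "growth_rate": 0.0, "grows": False,
                         "note": "not-in-model"})
            continue
        temp_rxn = None
        boundary = model.exchange_for_metabolite(cand)
        if boundary is None:
            temp_rxn = add_boundary_reaction(model, cand, kind="sink",
                                             rxn_id=f"__screen_sink_{cand}")
            boundary = temp_rxn.id
        medium = baseline.updated(
            {source_exchange: (0.0, baseline.bounds.get(source_exchange, (0, 1000))[1]),
             boundary: (-uptake, 1000.0)},
            name=f"{baseline.name}[{element}:{cand}]",
        )
        if boundary == source_exchange:  # candidate IS the baseline source
            medium = baseline.updated({}, name=medium.name)
        pheno, _ = simulate_condition(model, medium, objective_id)
        rows.append({"candidate": cand, "growth_rate": pheno.growth_rate,
                     "grows": pheno.grows, "note": ""})
        if temp_rxn is not None:
            model.remove_reaction(temp_rxn.id)
    assert model.to_dict() == before, "screen failed to restore the model"
    # ordering independence: rows are already sorted by candidate id
    return pd.DataFrame(rows)


def parameter_sweep(
    model: MetabolicModel,
    medium: Medium,
    parameter: str,
    grid,
    objective_id: str | None = None,
    tracked: list[str] = (),
) -> pd.DataFrame:
    """One FBA per grid point over a named parameter.

    ``parameter`` is either an exchange-reaction id (the grid sets its
    uptake: lower bound = -value) or ``"<rid>:upper"`` to sweep an upper
    bound.  ``tracked`` reactions' fluxes are reported alongside growth.
    """
    rows = []
    rid, _, which = parameter.partition(":")
    if rid not in model.reactions:
        raise KeyError(f"sweep parameter {rid!r} is not a reaction id")
    for value in grid:
        if which == "upper":
            override = {rid: (model.reactions[rid].lower_bound, float(value))}
        else:
            override = {rid: (-float(value), model.reactions[rid].upper_bound)}
        pheno, dist = simulate_condition(model, medium.updated(override), objective_id)
        row = {"value": float(value), "growth_rate": pheno.growth_rate,
               "grows": pheno.grows}
        for t in tracked:
            row[t] = dist.fluxes.get(t, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)
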