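"""Shared fixtures: toy networks and an independent LP oracle.

The oracle converts a model to COBRApy (optlang/GLPK backend), a solver
stack disjoint from the package's own scipy/HiGHS path, so agreement is a
genuine cross-check and not a tautology.
"""

from __future__ import annotations

import pytest

from rhodoflux import MetabolicModel, Metabolite, Reaction, mini_phototroph
from rhodoflux.synthetic_data import (
    medium_aerobic_snh3,
    medium_dark_dmso,
    medium_dark_no_acceptor,
    medium_photo_sglm,
    medium_photo_snh3,
)


@pytest.fixture(scope="session")
def mini():
    return mini_phototroph()


@pytest.fixture()
def photo_sglm():
    return medium_photo_sglm()


@pytest.fixture()
def photo_snh3():
    return medium_photo_snh3()


@pytest.fixture()
def aerobic_snh3():
    return medium_aerobic_snh3()


@pytest.fixture()
def dark_dmso():
    return medium_dark_dmso()


@pytest.fixture()
def dark_none():
    return medium_dark_no_acceptor()


def chain_model(uptake: float = 10.0) -> MetabolicModel:
    """EX_A (uptake) -> A -2-> B -> biomass(2 B): optimum = uptake."""
    m = MetabolicModel("chain")
    m.compartments = {"c": "c"}
    m.add_metabolite(Metabolite("A", compartment="c"))
    m.add_metabolite(Metabolite("B", compartment="c"))
    m.add_reaction(Reaction("EX_A", {"A": -1.0}, -uptake, 1000.0, category="exchange"))
    m.add_reaction(Reaction("R1", {"A": -1.0, "B": 2.0}, 0.0, 1000.0))
    m.add_reaction(Reaction("BIOMASS", {"B": -2.0}, 0.0, 1000.0, category="biomass"))
    m.objective_reaction_id = "BIOMASS"
    return m


def parallel_sink_model() -> MetabolicModel:
    """Uptake feeds biomass plus an obligatory byproduct with two
    interchangeable disposal sinks: a two-pattern degenerate optimum."""
    m = MetabolicModel("parallel_sinks")
    m.compartments = {"c": "c"}
    for mid in ["A", "P", "B"]:
        m.add_metabolite(Metabolite(mid, compartment="c"))
    m.add_reaction(Reaction("EX_A", {"A": -1.0}, -10.0, 1000.0, category="exchange"))
    m.add_reaction(Reaction("SPLIT", {"A": -1.0, "P": 1.0, "B": 1.0}))
    m.add_reaction(Reaction("s1", {"B": -1.0}, 0.0, 1000.0, category="demand"))
    m.add_reaction(Reaction("s2", {"B": -1.0}, 0.0, 1000.0, category="demand"))
    m.add_reaction(Reaction("BIOMASS", {"P": -1.0}, 0.0, 1000.0, category="biomass"))
    m.objective_reaction_id = "BIOMASS"
    return m


def to_cobra(model: MetabolicModel, medium=None):
    """Convert to a COBRApy model solved with GLPK (the independent oracle)."""
    import cobra

    cm = cobra.Model(model.id)
    cm.add_metabolites(
        [cobra.Metabolite(mid, compartment=met.compartment)
         for mid, met in model.metabolites.items()]
    )
    overrides = dict(medium.bounds) if medium is not None and hasattr(medium, "bounds") \
        else dict(medium or {})
    rxns = []
    for rid, r in model.reactions.items():
        cr = cobra.Reaction(rid)
        lb, ub = overrides.get(rid, (r.lower_bound, r.upper_bound))
        cr.lower_bound, cr.upper_bound = lb, ub
        rxns.append(cr)
    cm.add_reactions(rxns)
    for rid, r in model.reactions.items():
        cm.reactions.get_by_id(rid).add_metabolites(
            {cm.metabolites.get_by_id(k): v for k, v in r.stoichiometry.items()}
        )
    if model.objective_reaction_id:
        cm.objective = cm.reactions.get_by_id(model.objective_reaction_id)
    cm.solver = "glpk"
    return cm
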