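"""FBA/FVA correctness, blocked-reaction and balanced-cycle detection."""

import numpy as np
import pytest

from rhodoflux import (
    MetabolicModel,
    Metabolite,
    Reaction,
    detect_sbcs,
    fba,
    find_blocked,
    fva,
)
from rhodoflux.lp_engine import check_flux_distribution
from rhodoflux.synthetic_data import MINI_PHOTO_SGLM_OPTIMUM

from .conftest import chain_model, to_cobra


def test_fba_chain_conservation():
    """Uptake 10 of A, A -> 2B, biomass drains 2B: conservation forces 10."""
    dist = fba(chain_model(10.0))
    assert dist.optimal
    assert dist.objective_value == pytest.approx(10.0, abs=1e-9)


def test_fba_infeasible_without_energy_source():
    m = chain_model()
    m.add_metabolite(Metabolite("atp", compartment="c"))
    m.add_reaction(Reaction("MK_atp", {"A": -1.0, "atp": 1.0}))
    m.add_reaction(Reaction("NGAM", {"atp": -1.0}, 1.0, 1.0))
    dist = fba(m, medium={"EX_A": (0.0, 1000.0)})  # everything closed
    assert dist.status == "infeasible"


def test_optimal_solution_satisfies_constraints(mini, photo_sglm):
    dist = fba(mini, photo_sglm)
    assert dist.optimal
    assert check_flux_distribution(mini, dist, photo_sglm) <= 1e-6
    from rhodoflux.lp_engine import build_lp

    _, rxn_ids, lb, ub = build_lp(mini, photo_sglm)
    v = np.array([dist.fluxes[r] for r in rxn_ids])
    assert np.all(v >= lb - 1e-9) and np.all(v <= ub + 1e-9)


def test_fba_matches_glpk_oracle(mini, photo_sglm):
    cm = to_cobra(mini, photo_sglm)
    oracle = cm.optimize().objective_value
    ours = fba(mini, photo_sglm).objective_value
    assert ours == pytest.approx(oracle, abs=1e-7)
    assert ours == pytest.approx(MINI_PHOTO_SGLM_OPTIMUM, abs=1e-9)


def _duplicate_pathway_model():
    m = MetabolicModel("dup")
    for mid in ["A", "B"]:
        m.add_metabolite(Metabolite(mid, compartment="c"))
    m.add_reaction(Reaction("EX_A", {"A": -1.0}, -10.0, 1000.0, category="exchange"))
    m.add_reaction(Reaction("R1a", {"A": -1.0, "B": 1.0}, 0.0, 1000.0))
    m.add_reaction(Reaction("R1b", {"A": -1.0, "B": 1.0}, 0.0, 1000.0))
    m.add_reaction(Reaction("BIOMASS", {"B": -1.0}, 0.0, 1000.0, category="biomass"))
    m.objective_reaction_id = "BIOMASS"
    return m


def test_fva_symmetric_parallel_reactions():
    """Two duplicate routes carrying a required total of 10 each range (0, 10)."""
    res = fva(_duplicate_pathway_model())
    for rid in ("R1a", "R1b"):
        lo, hi = res.ranges[rid]
        assert lo == pytest.approx(0.0, abs=1e-6)
        assert hi == pytest.approx(10.0, abs=1e-5)


def test_fva_objective_range_is_point(mini, photo_sglm):
    res = fva(mini, photo_sglm, reactions=["BIOMASS"])
    lo, hi = res.ranges["BIOMASS"]
    Z = res.objective_fixed_at
    assert lo == pytest.approx(Z, rel=1e-5)
    assert hi == pytest.approx(Z, rel=1e-5)


def test_fva_dead_end_is_zero(mini, photo_sglm):
    res = fva(mini, photo_sglm, reactions=["DEAD_RXN"])
    assert res.ranges["DEAD_RXN"] == (0.0, 0.0)


def test_fva_matches_glpk_oracle_on_mini(mini, photo_sglm):
    from cobra.flux_analysis import flux_variability_analysis

    subset = ["EX_h2", "EX_h2s", "DM_phb", "NDH", "EX_co2"]
    ours = fva(mini, photo_sglm, reactions=subset)
    cm = to_cobra(mini, photo_sglm)
    oracle = flux_variability_analysis(cm, reaction_list=subset, fraction_of_optimum=1.0)
    for rid in subset:
        lo, hi = ours.ranges[rid]
        assert lo == pytest.approx(oracle.loc[rid, "minimum"], abs=2e-4)
        assert hi == pytest.approx(oracle.loc[rid, "maximum"], abs=2e-4)


def test_find_blocked(mini):
    assert find_blocked(mini, "open") == {"DEAD_RXN"}
    assert find_blocked(chain_model(), "open") == set()


def test_orphan_consumer_is_blocked():
    m = chain_model()
    m.add_metabolite(Metabolite("orphan", compartment="c"))
    m.add_reaction(Reaction("USE_ORPHAN", {"orphan": -1.0, "B": 1.0}))
    assert find_blocked(m, "open") == {"USE_ORPHAN"}


def _three_cycle(irreversible_against=False):
    m = MetabolicModel("cycle")
    for i in range(3):
        m.add_metabolite(Metabolite(f"C{i}", compartment="c"))
    m.add_metabolite(Metabolite("X", compartment="c"))
    m.add_reaction(Reaction("EX_X", {"X": -1.0}, -10.0, 1000.0, category="exchange"))
    m.add_reaction(Reaction("FEED", {"X": -1.0, "C0": 1.0}))
    m.add_reaction(Reaction("OUT", {"C0": -1.0}, 0.0, 1000.0, category="demand"))
    for i in range(3):
        lb = -1000.0
        if irreversible_against and i == 1:
            lb = 0.0  # C1 -> C2 only: the loop direction C2->C1 is cut
        m.add_reaction(Reaction(f"L{i}", {f"C{i}": -1.0, f"C{(i + 1) % 3}": 1.0},
                                lb, 1000.0))
    m.objective_reaction_id = "OUT"
    return m


def test_detect_sbcs_planted_cycle():
    groups = detect_sbcs(_three_cycle())
    assert groups == [{"L0", "L1", "L2"}]


def test_detect_sbcs_direction_cut():
    """A reversible 3-cycle is an SBC; making one edge irreversible leaves a
    consistent direction, which still cycles — cutting needs two edges or an
    opposing irreversible edge.  With L1 irreversible the loop can still run
    forward, so only forcing an opposing direction kills it."""
    m = _three_cycle()
    # forward-only everywhere: the loop still turns (all same direction)
    for rid in ("L0", "L1", "L2"):
        m.reactions[rid].lower_bound = 0.0
    assert detect_sbcs(m) == [{"L0", "L1", "L2"}]
    # one reaction reversed against the cycle: no balanced flux possible
    m.reactions["L1"].stoichiometry = {"C2": -1.0, "C1": 1.0}
    m.reactions["L1"].lower_bound = 0.0
    assert detect_sbcs(m) == []


def test_detect_sbcs_loop_free_chain(mini):
    assert detect_sbcs(chain_model()) == []
    assert detect_sbcs(mini) == []


def test_closed_exchanges_on_sbc_free_model_zero_space():
    """With all exchanges closed an SBC-free network admits only v = 0."""
    m = chain_model()
    closed = {rid: (0.0, 0.0) for rid in m.boundary_reactions()}
    res = fva(m, closed, objective_id="BIOMASS")
    assert all(abs(lo) < 1e-9 and abs(hi) < 1e-9 for lo, hi in res.ranges.values())
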