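"""Core data model: GPR logic, SBML round trips, matrix construction."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhodoflux import (
    GprExpression,
    MetabolicModel,
    Metabolite,
    Reaction,
    add_boundary_reaction,
    build_matrix,
    evaluate_gpr,
    model_summary,
    read_sbml,
    write_sbml,
)
from rhodoflux.model_core import GprError, check_mass_balance

from .conftest import chain_model


# ---------------------------------------------------------------------------
# GPR
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "rule, knocked, active",
    [
        ("(g1 and g2) or g3", {"g1"}, True),  # isozyme g3 rescues
        ("g1 and g2", {"g2"}, False),
        ("", {"g1", "g2", "g3"}, True),  # no gene association: never knockable
        ("g1 or g2", {"g1", "g2"}, False),
        ("(g1 or g2) and (g3 or g4)", {"g1", "g3"}, True),
        ("g1 AND g2", set(), True),  # case-insensitive keywords
    ],
)
def test_gpr_evaluation(rule, knocked, active):
    assert evaluate_gpr(rule, knocked) is active


@pytest.mark.parametrize("bad", ["g1 and", "(g1 or g2", "and g1", "g1 ) g2"])
def test_malformed_gpr_fails_loudly(bad):
    with pytest.raises(GprError):
        GprExpression.parse(bad)


def _gpr_tree(depth):
    leaf = st.integers(0, 5).map(lambda i: f"g{i}")
    return st.recursive(
        leaf,
        lambda children: st.tuples(
            st.sampled_from(["and", "or"]),
            st.lists(children, min_size=2, max_size=3).map(tuple),
        ),
        max_leaves=10,
    )


def _truth_table_eval(node, knocked):
    """Independent brute-force evaluator used as the oracle."""
    if isinstance(node, str):
        return node not in knocked
    op, children = node
    values = [_truth_table_eval(c, knocked) for c in children]
    return all(values) if op == "and" else any(values)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(_gpr_tree(3))
def test_gpr_matches_truth_table(tree):
    expr = GprExpression(tree)
    genes = sorted(expr.genes())
    assert len(genes) <= 10
    for r in range(len(genes) + 1):
        for combo in itertools.combinations(genes, r):
            knocked = frozenset(combo)
            assert expr.evaluate(knocked) == _truth_table_eval(tree, knocked)
    # string round trip preserves semantics
    reparsed = GprExpression.parse(expr.to_string())
    assert reparsed.evaluate(frozenset(genes[:1])) == expr.evaluate(frozenset(genes[:1]))


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

def test_sbml_round_trip_mini(mini, tmp_path):
    path = tmp_path / "mini.xml"
    write_sbml(mini, path)
    again = read_sbml(path)
    assert again == mini  # stoichiometry, bounds, GPR, categories, objective


def test_sbml_round_trip_chain_and_gpr(tmp_path):
    m = chain_model()
    m.reactions["R1"].gpr = GprExpression.parse("(g1 and g2) or g3")
    path = tmp_path / "chain.xml"
    write_sbml(m, path)
    again = read_sbml(path)
    assert again == m
    assert again.reactions["R1"].gpr.to_string() == "(g1 and g2) or g3"


def test_sbml_empty_model_skeleton(tmp_path):
    m = MetabolicModel("empty")
    path = tmp_path / "empty.xml"
    write_sbml(m, path)
    again = read_sbml(path)
    assert len(again.reactions) == 0 and len(again.metabolites) == 0


_LEGACY_L2 = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2" level="2" version="1">
 <model id="legacy">
  <listOfCompartments><compartment id="c"/></listOfCompartments>
  <listOfSpecies>
   <species id="A" compartment="c"/>
   <species id="B" compartment="c"/>
  </listOfSpecies>
  <listOfReactions>
   <reaction id="R_free" reversible="true">
    <listOfReactants><speciesReference species="A"/></listOfReactants>
    <listOfProducts><speciesReference species="B"/></listOfProducts>
   </reaction>
   <reaction id="R_capped" reversible="true">
    <notes><body xmlns="http://www.w3.org/1999/xhtml">
      <p>GENE_ASSOCIATION: (g1 and g2) or g3</p></body></notes>
    <listOfReactants><speciesReference species="B"/></listOfReactants>
    <listOfProducts><speciesReference species="A"/></listOfProducts>
    <kineticLaw>
     <math xmlns="http://www.w3.org/1998/Math/MathML"><ci> FLUX_VALUE </ci></math>
     <listOfParameters>
      <parameter id="LOWER_BOUND" value="-5"/>
      <parameter id="UPPER_BOUND" value="7"/>
      <parameter id="FLUX_VALUE" value="0"/>
     </listOfParameters>
    </kineticLaw>
   </reaction>
  </listOfReactions>
 </model>
</sbml>
"""


def test_legacy_l2_dialect(tmp_path):
    """2011-style SBML: kinetic-law bounds, notes GPR, reversibility default."""
    path = tmp_path / "legacy.xml"
    path.write_text(_LEGACY_L2)
    m = read_sbml(path)
    # reversible reaction with no explicit bounds defaults to the box
    assert (m.reactions["R_free"].lower_bound, m.reactions["R_free"].upper_bound) == (-1000.0, 1000.0)
    assert (m.reactions["R_capped"].lower_bound, m.reactions["R_capped"].upper_bound) == (-5.0, 7.0)
    assert m.reactions["R_capped"].gpr.to_string() == "(g1 and g2) or g3"


def test_unparsable_sbml_is_hard_error(tmp_path):
    path = tmp_path / "junk.xml"
    path.write_text("this is not SBML")
    with pytest.raises(IOError):
        read_sbml(path)


# ---------------------------------------------------------------------------
# Matrix, summary, boundary edits
# ---------------------------------------------------------------------------

def test_build_matrix_column():
    m = MetabolicModel("m")
    m.add_metabolite(Metabolite("A", compartment="c"))
    m.add_metabolite(Metabolite("B", compartment="c"))
    m.add_reaction(Reaction("R", {"A": -1.0, "B": 2.0}))
    S, mets, rxns = build_matrix(m)
    assert S.shape == (2, 1) and mets == ["A", "B"] and rxns == ["R"]
    assert S.toarray().ravel().tolist() == [-1.0, 2.0]


def test_build_matrix_empty_and_mini(mini):
    S, _, _ = build_matrix(MetabolicModel("z"))
    assert S.shape == (0, 0)
    S, mets, rxns = build_matrix(mini)
    assert S.shape == (len(mini.metabolites), len(mini.reactions))


def test_model_summary(mini):
    s = model_summary(mini)
    assert s["reactions"] == len(mini.reactions)
    assert s["reversible"] + s["irreversible"] == s["reactions"]
    assert s["reaction_categories"]["exchange"] == 12
    assert s["reaction_categories"]["demand"] == 2
    assert s["reaction_categories"]["biomass"] == 1
    empty = model_summary(MetabolicModel("z"))
    assert empty["reactions"] == 0 and empty["genes"] == 0


def test_add_remove_boundary_restores_model(mini):
    m = mini.copy()
    before = m.to_dict()
    rxn = add_boundary_reaction(m, "phb", kind="sink")
    assert rxn.lower_bound < 0 < rxn.upper_bound  # sinks are reversible
    m.remove_reaction(rxn.id)
    assert m.to_dict() == before


def test_boundary_errors(mini):
    m = mini.copy()
    with pytest.raises(KeyError):
        add_boundary_reaction(m, "no_such_met")
    add_boundary_reaction(m, "phb", kind="demand", rxn_id="DM_phb2")
    with pytest.raises(ValueError):
        m.add_reaction(Reaction("DM_phb2", {"phb": -1.0}))


def test_mass_balance_on_fixture(mini):
    """Transport reactions with full formulas must be elementally balanced;
    reactions touching formula-less carriers are skipped (None)."""
    checked = 0
    for rid in mini.reactions:
        rxn = mini.reactions[rid]
        if rxn.is_boundary() or rxn.category == "biomass":
            continue
        net = check_mass_balance(mini, rid)
        if net is not None:
            assert net == {}, f"{rid} unbalanced: {net}"
            checked += 1
    assert checked >= 10  # the transport reactions at least
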