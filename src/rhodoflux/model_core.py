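"""Data model for genome-scale metabolic networks.

Defines metabolites, reactions with flux bounds and boolean
gene-protein-reaction (GPR) rules, the container :class:`MetabolicModel`,
stoichiometric-matrix construction, SBML read/write (Level 3 + fbc, with a
legacy Level 2 read fallback for the 2011 COBRA dialect) and small editing
helpers such as boundary-reaction insertion.

Sign conventions
----------------
Stoichiometric coefficients are negative for consumed metabolites.  Exchange
reactions are written as ``metabolite_e ->`` so positive flux is secretion
and negative flux is uptake; the default exchange bounds ``(0, 1000)`` allow
secretion only, and a growth medium opens the lower bound to minus the
uptake rate.  Flux units are mmol/gDW/h (the biomass reaction in 1/h).
"""

from __future__ import annotations

import json
import math
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from ._formula import _ELECTRONS, parse_formula

DEFAULT_BOUND = 1000.0

REACTION_CATEGORIES = (
    "transformation",
    "transport",
    "exchange",
    "demand",
    "sink",
    "biomass",
)


# ---------------------------------------------------------------------------
# GPR expressions
# ---------------------------------------------------------------------------

class GprError(ValueError):
    """Raised for malformed GPR strings (they fail loudly, never silently)."""


@dataclass(frozen=True)
class GprExpression:
    """Boolean expression tree over gene ids.

    ``node`` is ``None`` (empty rule, always active), a gene-id string, or a
    tuple ``("and"| "or", (children...))``.  AND encodes a multi-subunit
    complex, OR encodes isozymes.
    """

    node: object = None

    @staticmethod
    def parse(text: str | None) -> "GprExpression":
        """Parse a case-insensitive ``and``/``or`` rule with parentheses."""
        if text is None or not text.strip():
            return GprExpression(None)
        tokens = re.findall(r"\(|\)|[^\s()]+", text)
        pos = 0

        def peek():
            return tokens[pos] if pos < len(tokens) else None

        def parse_or():
            nonlocal pos
            terms = [parse_and()]
            while peek() is not None and peek().lower() == "or":
                pos += 1
                terms.append(parse_and())
            return terms[0] if len(terms) == 1 else ("or", tuple(terms))

        def parse_and():
            nonlocal pos
            terms = [parse_atom()]
            while peek() is not None and peek().lower() == "and":
                pos += 1
                terms.append(parse_atom())
            return terms[0] if len(terms) == 1 else ("and", tuple(terms))

        def parse_atom():
            nonlocal pos
            tok = peek()
            if tok is None:
                raise GprError(f"truncated GPR: {text!r}")
            if tok == "(":
                pos += 1
                inner = parse_or()
                if peek() != ")":
                    raise GprError(f"unbalanced parentheses in GPR: {text!r}")
                pos += 1
                return inner
            if tok == ")" or tok.lower() in ("and", "or"):
                raise GprError(f"malformed GPR: {text!r}")
            pos += 1
            return tok

        node = parse_or()
        if pos != len(tokens):
            raise GprError(f"trailing tokens in GPR: {text!r}")
        return GprExpression(node)

    def is_empty(self) -> bool:
        return self.node is None

    def genes(self) -> frozenset[str]:
        out: set[str] = set()

        def walk(n):
            if n is None:
                return
            if isinstance(n, str):
                out.add(n)
            else:
                for c in n[1]:
                    walk(c)

        walk(self.node)
        return frozenset(out)

    def evaluate(self, knocked: set[str] | frozenset[str] = frozenset()) -> bool:
        """True iff the reaction remains catalyzable with ``knocked`` deleted.

        An empty rule evaluates True: reactions without gene association can
        never be knocked out at the gene level.
        """

        def walk(n) -> bool:
            if n is None:
                return True
            if isinstance(n, str):
                return n not in knocked
            op, children = n
            if op == "and":
                return all(walk(c) for c in children)
            return any(walk(c) for c in children)

        return walk(self.node)

    def to_string(self) -> str:
        def walk(n, parent_op=None) -> str:
            if n is None:
                return ""
            if isinstance(n, str):
                return n
            op, children = n
            inner = f" {op} ".join(walk(c, op) for c in children)
            if parent_op is not None and parent_op != op:
                return f"({inner})"
            return inner

        return walk(self.node)


def evaluate_gpr(gpr: GprExpression | str | None, knocked) -> bool:
    """Convenience wrapper accepting a rule string or expression tree."""
    if not isinstance(gpr, GprExpression):
        gpr = GprExpression.parse(gpr)
    return gpr.evaluate(frozenset(knocked))


# ---------------------------------------------------------------------------
# Core types
# ---------------------------------------------------------------------------

@dataclass
class Metabolite:
    id: str
    name: str = ""
    formula: str | None = None
    charge: int | None = None
    compartment: str = "c"


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: GprExpression = field(default_factory=GprExpression)
    subsystem: str = ""
    category: str = "transformation"
    name: str = ""

    def __post_init__(self):
        if isinstance(self.gpr, str) or self.gpr is None:
            self.gpr = GprExpression.parse(self.gpr)
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if self.category not in REACTION_CATEGORIES:
            raise ValueError(f"reaction {self.id}: unknown category {self.category!r}")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def is_boundary(self) -> bool:
        return self.category in ("exchange", "demand", "sink")

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


class MetabolicModel:
    """A stoichiometric metabolic network.

    Reactions and metabolites preserve insertion order; that order defines
    the rows and columns of the stoichiometric matrix.
    """

    def __init__(self, model_id: str = "model", name: str = ""):
        self.id = model_id
        self.name = name
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.compartments: dict[str, str] = {}
        self.objective_reaction_id: str | None = None

    # -- construction -------------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ValueError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met
        self.compartments.setdefault(met.compartment, met.compartment)
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id {rxn.id!r}")
        for mid in rxn.stoichiometry:
            if mid not in self.metabolites:
                raise ValueError(
                    f"reaction {rxn.id!r} references unknown metabolite {mid!r}"
                )
        self.reactions[rxn.id] = rxn
        return rxn

    def remove_reaction(self, rxn_id: str) -> Reaction:
        if rxn_id not in self.reactions:
            raise KeyError(rxn_id)
        if rxn_id == self.objective_reaction_id:
            self.objective_reaction_id = None
        return self.reactions.pop(rxn_id)

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for rxn in self.reactions.values():
            out |= rxn.gpr.genes()
        return frozenset(out)

    def copy(self) -> "MetabolicModel":
        m = MetabolicModel(self.id, self.name)
        m.compartments = dict(self.compartments)
        for met in self.metabolites.values():
            m.metabolites[met.id] = replace(met)
        for rxn in self.reactions.values():
            m.reactions[rxn.id] = rxn.copy()
        m.objective_reaction_id = self.objective_reaction_id
        return m

    # -- queries ------------------------------------------------------------

    def boundary_reactions(self) -> list[str]:
        return [r.id for r in self.reactions.values() if r.is_boundary()]

    def exchanges(self) -> list[str]:
        return [r.id for r in self.reactions.values() if r.category == "exchange"]

    def reactions_for_gene(self, gene: str) -> list[str]:
        return [r.id for r in self.reactions.values() if gene in r.gpr.genes()]

    def exchange_for_metabolite(self, met_id: str) -> str | None:
        for rxn in self.reactions.values():
            if rxn.is_boundary() and set(rxn.stoichiometry) == {met_id}:
                return rxn.id
        return None

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        return self.to_dict() == other.to_dict()

    def to_dict(self) -> dict:
        """JSON-serializable dump of every field the pipeline uses."""
        return {
            "id": self.id,
            "name": self.name,
            "compartments": dict(self.compartments),
            "objective": self.objective_reaction_id,
            "metabolites": [
                {
                    "id": m.id, "name": m.name, "formula": m.formula,
                    "charge": m.charge, "compartment": m.compartment,
                }
                for m in self.metabolites.values()
            ],
            "reactions": [
                {
                    "id": r.id, "name": r.name,
                    "stoichiometry": dict(sorted(r.stoichiometry.items())),
                    "lower_bound": r.lower_bound, "upper_bound": r.upper_bound,
                    "gpr": r.gpr.to_string(), "subsystem": r.subsystem,
                    "category": r.category,
                }
                for r in self.reactions.values()
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def build_matrix(model: MetabolicModel):
    """Stoichiometric matrix S with ordered row/column keys.

    Returns ``(S, metabolite_ids, reaction_ids)`` where ``S`` is a CSR sparse
    matrix of shape (n_metabolites, n_reactions) and entry (i, j) is the
    coefficient of metabolite i in reaction j.
    """
    met_ids = list(model.metabolites)
    rxn_ids = list(model.reactions)
    met_index = {m: i for i, m in enumerate(met_ids)}
    rows, cols, vals = [], [], []
    for j, rid in enumerate(rxn_ids):
        for mid, coeff in model.reactions[rid].stoichiometry.items():
            rows.append(met_index[mid])
            cols.append(j)
            vals.append(coeff)
    S = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids)), dtype=float
    )
    return S, met_ids, rxn_ids


def model_summary(model: MetabolicModel) -> dict:
    """Count table: genes, metabolites per compartment, reaction categories,
    reversibility split."""
    per_comp: dict[str, int] = {}
    for met in model.metabolites.values():
        per_comp[met.compartment] = per_comp.get(met.compartment, 0) + 1
    categories = {c: 0 for c in REACTION_CATEGORIES}
    n_rev = n_irrev = n_gpr = 0
    for rxn in model.reactions.values():
        categories[rxn.category] += 1
        if rxn.reversible:
            n_rev += 1
        else:
            n_irrev += 1
        if not rxn.gpr.is_empty():
            n_gpr += 1
    return {
        "genes": len(model.genes),
        "metabolites": len(model.metabolites),
        "metabolites_per_compartment": per_comp,
        "reactions": len(model.reactions),
        "reaction_categories": categories,
        "reversible": n_rev,
        "irreversible": n_irrev,
        "with_gpr": n_gpr,
    }


def add_boundary_reaction(
    model: MetabolicModel,
    met_id: str,
    kind: str = "exchange",
    bounds: tuple[float, float] | None = None,
    rxn_id: str | None = None,
) -> Reaction:
    """Append a single-metabolite boundary reaction ``met ->``.

    ``demand`` is irreversible efflux (0, 1000); ``sink`` is reversible
    (-1000, 1000); ``exchange`` defaults to secretion-only (0, 1000).
    """
    if met_id not in model.metabolites:
        raise KeyError(f"unknown metabolite {met_id!r}")
    if kind not in ("exchange", "demand", "sink"):
        raise ValueError(f"kind must be exchange|demand|sink, got {kind!r}")
    if bounds is None:
        bounds = (-DEFAULT_BOUND, DEFAULT_BOUND) if kind == "sink" else (0.0, DEFAULT_BOUND)
    prefix = {"exchange": "EX", "demand": "DM", "sink": "SK"}[kind]
    rid = rxn_id or f"{prefix}_{met_id}"
    rxn = Reaction(
        id=rid,
        stoichiometry={met_id: -1.0},
        lower_bound=bounds[0],
        upper_bound=bounds[1],
        category=kind,
    )
    return model.add_reaction(rxn)


def check_mass_balance(model: MetabolicModel, rxn_id: str) -> dict[str, float] | None:
    """Net elemental imbalance of a non-boundary reaction, or None if any
    participating metabolite lacks a formula."""
    net: dict[str, float] = {}
    rxn = model.reactions[rxn_id]
    for mid, coeff in rxn.stoichiometry.items():
        formula = model.metabolites[mid].formula
        if not formula:
            return None
        for element, n in parse_formula(formula).items():
            net[element] = net.get(element, 0.0) + coeff * n
    return {e: v for e, v in net.items() if abs(v) > 1e-9}


# ---------------------------------------------------------------------------
# SBML I/O (Level 3 + fbc primary; legacy Level 2 read fallback)
# ---------------------------------------------------------------------------

_NOTE_RE = re.compile(r"<p>\s*([A-Z_]+)\s*:\s*(.*?)\s*</p>", re.S | re.I)


def _notes_dict(sbase) -> dict[str, str]:
    notes = sbase.getNotesString() if sbase.isSetNotes() else ""
    return {k.upper(): v for k, v in _NOTE_RE.findall(notes)}


def _set_notes(sbase, entries: dict[str, str]) -> None:
    if not entries:
        return
    body = "".join(f"<p>{k}: {v}</p>" for k, v in entries.items())
    sbase.setNotes(
        f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'
    )


def _infer_category(rxn: Reaction, model: MetabolicModel) -> str:
    if len(rxn.stoichiometry) == 1:
        (mid,) = rxn.stoichiometry
        comp = model.metabolites[mid].compartment
        if rxn.id.startswith("DM_"):
            return "demand"
        if rxn.id.startswith("SK_") or rxn.id.startswith("sink_"):
            return "sink"
        if comp == "e" or comp.lower().startswith("extra") or rxn.id.startswith("EX_"):
            return "exchange"
        return "demand" if rxn.lower_bound >= 0 else "sink"
    return "transformation"


def read_sbml(path) -> MetabolicModel:
    """Read an SBML model (L3+fbc, or legacy L2 with kinetic-law bounds).

    Missing bounds default from the reversibility flag (±1000 or 0/1000).
    Unresolvable fbc gene references produce a warning and an empty GPR.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getModel() is None or doc.getNumErrors() > 0 and any(
        doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        for i in range(doc.getNumErrors())
    ):
        raise IOError(f"unparsable SBML file: {path}")
    smodel = doc.getModel()
    fbc = smodel.getPlugin("fbc")

    model = MetabolicModel(smodel.getId() or "model", smodel.getName() or "")
    for i in range(smodel.getNumCompartments()):
        comp = smodel.getCompartment(i)
        model.compartments[comp.getId()] = comp.getName() or comp.getId()

    gene_names: dict[str, str] = {}
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            gene_names[gp.getIdAttribute()] = gp.getLabel() or gp.getIdAttribute()

    for i in range(smodel.getNumSpecies()):
        sp_ = smodel.getSpecies(i)
        if sp_.getBoundaryCondition():
            continue  # boundary species are implicit in our convention
        sfbc = sp_.getPlugin("fbc")
        formula = None
        charge = None
        if sfbc is not None:
            if sfbc.isSetChemicalFormula():
                formula = sfbc.getChemicalFormula() or None
            if sfbc.isSetCharge():
                charge = sfbc.getCharge()
        notes = _notes_dict(sp_)
        if formula is None and "FORMULA" in notes:
            formula = notes["FORMULA"] or None
        if charge is None and sp_.isSetCharge():  # L2 legacy
            charge = sp_.getCharge()
        model.add_metabolite(
            Metabolite(
                id=sp_.getId(),
                name=sp_.getName() or "",
                formula=formula,
                charge=charge,
                compartment=sp_.getCompartment() or "c",
            )
        )

    def parameter_value(pid):
        p = smodel.getParameter(pid)
        return p.getValue() if p is not None else None

    objective_id = None
    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getActiveObjective() or fbc.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            objective_id = obj.getFluxObjective(0).getReaction()

    for i in range(smodel.getNumReactions()):
        srxn = smodel.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(srxn.getNumReactants()):
            ref = srxn.getReactant(j)
            if ref.getSpecies() in model.metabolites:
                stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(srxn.getNumProducts()):
            ref = srxn.getProduct(j)
            if ref.getSpecies() in model.metabolites:
                stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0.0}

        reversible = srxn.getReversible()
        lb = -DEFAULT_BOUND if reversible else 0.0
        ub = DEFAULT_BOUND

        rfbc = srxn.getPlugin("fbc")
        if rfbc is not None and rfbc.isSetLowerFluxBound():
            v = parameter_value(rfbc.getLowerFluxBound())
            if v is not None:
                lb = max(v, -DEFAULT_BOUND) if math.isfinite(v) else -DEFAULT_BOUND
        if rfbc is not None and rfbc.isSetUpperFluxBound():
            v = parameter_value(rfbc.getUpperFluxBound())
            if v is not None:
                ub = min(v, DEFAULT_BOUND) if math.isfinite(v) else DEFAULT_BOUND
        # legacy COBRA dialect: bounds as kinetic-law parameters
        klaw = srxn.getKineticLaw()
        if klaw is not None:
            for j in range(klaw.getNumParameters()):
                p = klaw.getParameter(j)
                if p.getId() == "LOWER_BOUND":
                    lb = p.getValue()
                elif p.getId() == "UPPER_BOUND":
                    ub = p.getValue()

        gpr = GprExpression()
        if rfbc is not None and rfbc.isSetGeneProductAssociation():
            gpa = rfbc.getGeneProductAssociation()

            def assoc_to_node(a):
                if a is None:
                    return None
                import libsbml as _l

                if isinstance(a, _l.GeneProductRef):
                    gid = a.getGeneProduct()
                    if gid not in gene_names:
                        warnings.warn(f"unresolvable gene reference {gid!r}")
                        return None
                    return gene_names[gid]
                op = "and" if isinstance(a, _l.FbcAnd) else "or"
                children = [
                    assoc_to_node(a.getAssociation(k))
                    for k in range(a.getNumAssociations())
                ]
                children = [c for c in children if c is not None]
                if not children:
                    return None
                return children[0] if len(children) == 1 else (op, tuple(children))

            gpr = GprExpression(assoc_to_node(gpa.getAssociation()))
        notes = _notes_dict(srxn)
        if gpr.is_empty() and "GENE_ASSOCIATION" in notes:
            try:
                gpr = GprExpression.parse(notes["GENE_ASSOCIATION"])
            except GprError:
                warnings.warn(
                    f"unresolvable gene association on {srxn.getId()!r}; dropped"
                )
                gpr = GprExpression()

        rxn = Reaction(
            id=srxn.getId(),
            name=srxn.getName() or "",
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            gpr=gpr,
            subsystem=notes.get("SUBSYSTEM", ""),
        )
        rxn.category = notes.get("CATEGORY", "").lower() or _infer_category(rxn, model)
        if rxn.category not in REACTION_CATEGORIES:
            rxn.category = _infer_category(rxn, model)
        model.add_reaction(rxn)
        if objective_id is None and notes.get("OBJECTIVE", "").lower() == "true":
            objective_id = rxn.id

    if objective_id in model.reactions:
        model.objective_reaction_id = objective_id
    elif objective_id is None:
        for rid, rxn in model.reactions.items():
            if rxn.category == "biomass":
                model.objective_reaction_id = rid
                break
    return model


def write_sbml(model: MetabolicModel, path) -> None:
    """Write the model as SBML Level 3 Version 1 with the fbc v2 package."""
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    smodel = doc.createModel()
    smodel.setId(model.id)
    smodel.setName(model.name)
    mfbc = smodel.getPlugin("fbc")
    mfbc.setStrict(False)

    for cid, cname in (model.compartments or {"c": "c"}).items():
        comp = smodel.createCompartment()
        comp.setId(cid)
        comp.setName(cname)
        comp.setConstant(True)

    for met in model.metabolites.values():
        sp_ = smodel.createSpecies()
        sp_.setId(met.id)
        sp_.setName(met.name)
        sp_.setCompartment(met.compartment)
        sp_.setHasOnlySubstanceUnits(False)
        sp_.setBoundaryCondition(False)
        sp_.setConstant(False)
        sfbc = sp_.getPlugin("fbc")
        if met.formula:
            sfbc.setChemicalFormula(met.formula)
        if met.charge is not None:
            sfbc.setCharge(int(met.charge))

    gene_ids = {}
    for gene in sorted(model.genes):
        gid = "G_" + re.sub(r"\W", "_", gene)
        gp = mfbc.createGeneProduct()
        gp.setIdAttribute(gid)
        gp.setLabel(gene)
        gene_ids[gene] = gid

    bound_params = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = smodel.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions.values():
        srxn = smodel.createReaction()
        srxn.setId(rxn.id)
        srxn.setName(rxn.name)
        srxn.setReversible(rxn.lower_bound < 0)
        srxn.setFast(False)
        for mid, coeff in rxn.stoichiometry.items():
            ref = srxn.createReactant() if coeff < 0 else srxn.createProduct()
            ref.setSpecies(mid)
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rfbc = srxn.getPlugin("fbc")
        rfbc.setLowerFluxBound(bound_param(rxn.lower_bound))
        rfbc.setUpperFluxBound(bound_param(rxn.upper_bound))
        if not rxn.gpr.is_empty():
            gpa = rfbc.createGeneProductAssociation()

            def node_to_assoc(n, parent):
                if isinstance(n, str):
                    ref = parent.createGeneProductRef()
                    ref.setGeneProduct(gene_ids[n])
                else:
                    op, children = n
                    grp = parent.createAnd() if op == "and" else parent.createOr()
                    for c in children:
                        node_to_assoc(c, grp)

            node_to_assoc(rxn.gpr.node, gpa)
        notes = {"CATEGORY": rxn.category}
        if rxn.subsystem:
            notes["SUBSYSTEM"] = rxn.subsystem
        _set_notes(srxn, notes)

    if model.objective_reaction_id is not None:
        obj = mfbc.createObjective()
        obj.setIdAttribute("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(model.objective_reaction_id)
        fo.setCoefficient(1.0)
        mfbc.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")


def summary_tsv(model: MetabolicModel, path) -> None:
    """Tab-separated export of the model summary counts."""
    s = model_summary(model)
    lines = ["field\tvalue"]
    for key in ("genes", "metabolites", "reactions", "reversible", "irreversible", "with_gpr"):
        lines.append(f"{key}\t{s[key]}")
    for comp, n in sorted(s["metabolites_per_compartment"].items()):
        lines.append(f"metabolites[{comp}]\t{n}")
    for cat, n in s["reaction_categories"].items():
        lines.append(f"reactions[{cat}]\t{n}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
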