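"""Desk-scale fixture networks with analytically known answers.

:func:`mini_phototroph` builds a ~40-reaction purple-bacterium cartoon:
photon uptake drives a cyclic electron transport chain (reaction center +
cytochrome bc1 analog) that pumps protons for ATP synthesis; succinate-like
(C4H6O4, 14 e-/mol) and glutamate-like (C5H9NO4, 18 e-/mol) carbon sources
are oxidized to CO2 and NADH; a reversible NADH dehydrogenase links the
quinone and NAD pools; excess reducing power leaves through nitrogenase H2,
sulfite-reductase H2S, PHB and glycogen sinks; biomass drains one
protein-like and one lipid-like precursor plus ATP.  All stoichiometry uses
small integers, every carbon-bearing species has a formula, and the network
is electron-closed, so LP optima and electron ledgers can be audited by
hand:

* photoheterotrophic growth on succinate (1.57) + glutamate (0.75)
  mmol/gDW/h has the planted optimum mu* = 0.75 1/h (nitrogen-limited),
  with max H2 at that optimum = 7*(1.57-0.75) - 4*0.75 = 2.74 mmol/gDW/h;
* at zero growth the full substrate reducing power 14*1.57 + 18*0.75 =
  35.48 e- mmol/gDW/h can leave as H2 (17.74 mmol/gDW/h);
* NADH dehydrogenase is essential on succinate + ammonia (its quinol pool
  cannot otherwise be reoxidized anaerobically) but only reduces growth on
  succinate + glutamate — conditional essentiality with an isozyme GPR.

:func:`random_network` plants a linear uptake-to-biomass pathway of known
yield and decorates it with feature flags (parallel sinks, a
stoichiometrically balanced loop, isozyme/complex GPRs, maintenance,
storage demands) plus blocked dead-end decoy reactions that cannot disturb
the planted optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biomass import COD_PER_MG_GLYCOGEN, COD_PER_MG_PHB, THETA_PHOTO
from .conditions import Medium
from .lp_engine import ZERO_FLUX_TOL, fba
from .model_core import MetabolicModel, Metabolite, Reaction

FREE = 1000.0


# ---------------------------------------------------------------------------
# Mini-phototroph
# ---------------------------------------------------------------------------

def mini_phototroph() -> MetabolicModel:
    """Hand-auditable phototroph cartoon (see module docstring)."""
    m = MetabolicModel("mini_phototroph", "mini phototroph fixture")
    m.compartments = {"c": "cytoplasm", "e": "extracellular"}

    def met(mid, formula=None, comp="c", charge=None, name=""):
        m.add_metabolite(Metabolite(mid, name or mid, formula, charge, comp))

    # extracellular / cytoplasmic species (formulas give the electron ledger)
    for mid, formula, charge in [
        ("photon", None, None), ("suc", "C4H6O4", 0), ("glm", "C5H9NO4", 0),
        ("nh3", "H3N", 0), ("so4", "O4S", -2), ("o2", "O2", 0),
        ("h2o", "H2O", 0), ("co2", "CO2", 0), ("h2", "H2", 0),
        ("h2s", "H2S", 0), ("dmso", "C2H6OS", 0), ("dms", "C2H6S", 0),
    ]:
        met(mid + "_e", formula, "e", charge)
        met(mid, formula, "c", charge)
    # storage polymers and biomass precursors
    met("phb", "C4H6O2")        # hydroxybutyryl unit, 18 e-
    met("glyc", "C6H10O5")      # glucosyl unit, 24 e-
    met("prot", "C5H9NO4")      # protein-like precursor, 18 e-
    met("lip", "C4H10O2")       # lipid-like precursor, 22 e-
    met("dead", "C4H6O4")       # dead-end decoy (no consumer)
    # carriers: redox/energy bookkeeping only, excluded from the ledger
    for mid in ["atp", "adp", "nad", "nadh", "q", "qh2", "c2red", "c2ox", "pmf"]:
        met(mid)

    def rxn(rid, stoich, lb=0.0, ub=FREE, gpr=None, category="transformation",
            subsystem=""):
        m.add_reaction(Reaction(rid, stoich, lb, ub, gpr, subsystem, category))

    # exchanges: secretion-only by default; media open specific uptakes
    for mid in ["photon", "suc", "glm", "nh3", "so4", "o2", "h2o", "co2",
                "h2", "h2s", "dmso", "dms"]:
        rxn(f"EX_{mid}", {f"{mid}_e": -1.0}, 0.0, FREE, category="exchange")

    # transport (water/gases diffuse without genes)
    rxn("T_photon", {"photon_e": -1, "photon": 1})
    rxn("T_suc", {"suc_e": -1, "suc": 1}, gpr="dctA", category="transport")
    rxn("T_glm", {"glm_e": -1, "glm": 1}, gpr="gltP", category="transport")
    rxn("T_nh3", {"nh3_e": -1, "nh3": 1}, -FREE, FREE, category="transport")
    rxn("T_so4", {"so4_e": -1, "so4": 1}, gpr="sulP", category="transport")
    rxn("T_o2", {"o2_e": -1, "o2": 1}, category="transport")
    rxn("T_h2o", {"h2o_e": -1, "h2o": 1}, -FREE, FREE, category="transport")
    rxn("T_co2", {"co2_e": -1, "co2": 1}, -FREE, FREE, category="transport")
    rxn("T_h2", {"h2": -1, "h2_e": 1}, category="transport")
    rxn("T_h2s", {"h2s": -1, "h2s_e": 1}, category="transport")
    rxn("T_dmso", {"dmso_e": -1, "dmso": 1}, gpr="dmsT", category="transport")
    rxn("T_dms", {"dms": -1, "dms_e": 1}, category="transport")
    # T_photon above is a plain transformation; keep transport category
    m.reactions["T_photon"].category = "transport"

    # catabolism: full oxidation to CO2, electrons onto NAD / quinone
    rxn("CAT_suc", {"suc": -1, "h2o": -4, "nad": -6, "q": -1,
                    "co2": 4, "nadh": 6, "qh2": 1},
        gpr="sdhA and sdhB", subsystem="TCA")
    rxn("CAT_glm", {"glm": -1, "h2o": -4, "nad": -9,
                    "co2": 5, "nh3": 1, "nadh": 9},
        gpr="aspC", subsystem="TCA")

    # cyclic photosynthetic electron transport + oxidative phosphorylation
    rxn("RC", {"photon": -1, "c2red": -2, "q": -1, "c2ox": 2, "qh2": 1},
        gpr="pufL and pufM", subsystem="Photosynthesis")
    rxn("FBC", {"qh2": -1, "c2ox": -2, "q": 1, "c2red": 2, "pmf": 2},
        gpr="fbcB and fbcC", subsystem="ETC")
    rxn("NDH", {"nadh": -1, "q": -1, "nad": 1, "qh2": 1, "pmf": 2},
        -FREE, FREE, gpr="ndh1 or ndh2", subsystem="ETC")
    rxn("COX", {"c2red": -4, "o2": -1, "c2ox": 4, "h2o": 2, "pmf": 4},
        gpr="coxA or ccoN", subsystem="ETC")
    rxn("QOX", {"qh2": -2, "o2": -1, "q": 2, "h2o": 2, "pmf": 2},
        gpr="qoxA or qxtA", subsystem="ETC")
    rxn("DMSOR", {"dmso": -1, "qh2": -1, "dms": 1, "q": 1, "h2o": 1},
        gpr="dmsA", subsystem="Anaerobic respiration")
    rxn("ATPS", {"adp": -1, "pmf": -3, "atp": 1},
        gpr="atpA and atpB", subsystem="ETC")

    # electron sinks
    rxn("NIT", {"nadh": -1, "atp": -4, "h2": 1, "nad": 1, "adp": 4},
        gpr="nifH and nifD and nifK", subsystem="Nitrogen metabolism")
    rxn("SIR", {"so4": -1, "nadh": -4, "atp": -1,
                "h2s": 1, "nad": 4, "adp": 1, "h2o": 4},
        gpr="cysI", subsystem="Sulfur metabolism")
    rxn("PHBS", {"suc": -1, "nadh": -2, "phb": 1, "nad": 2, "h2o": 2},
        gpr="phaC", subsystem="Butanoate metabolism")
    rxn("GLGS", {"co2": -6, "nadh": -12, "atp": -18,
                 "glyc": 1, "nad": 12, "adp": 18, "h2o": 7},
        gpr="glgA and (cbbL or cbbM)", subsystem="Carbon fixation")
    rxn("DM_phb", {"phb": -1}, 0.0, FREE, category="demand")
    rxn("DM_glyc", {"glyc": -1}, 0.0, FREE, category="demand")

    # anabolism and biomass
    rxn("PSYN_glm", {"glm": -1, "atp": -1, "prot": 1, "adp": 1},
        gpr="pepA", subsystem="Protein synthesis")
    rxn("PSYN_nh3", {"suc": -1, "co2": -1, "nh3": -1, "nadh": -2, "atp": -3,
                     "prot": 1, "nad": 2, "adp": 3, "h2o": 2},
        gpr="gdhA", subsystem="Protein synthesis")
    rxn("LSYN", {"suc": -1, "nadh": -4, "atp": -1,
                 "lip": 1, "nad": 4, "adp": 1, "h2o": 2},
        gpr="fabF and fabG", subsystem="Lipid synthesis")
    rxn("BIOMASS", {"prot": -1, "lip": -1, "atp": -10, "adp": 10},
        0.0, FREE, category="biomass")
    rxn("ATPM", {"atp": -1, "adp": 1}, 0.5, 0.5, subsystem="Maintenance")
    rxn("DEAD_RXN", {"suc": -1, "dead": 1}, gpr="deadG")

    m.objective_reaction_id = "BIOMASS"
    return m


#: Planted photoheterotrophic optimum on succinate 1.57 + glutamate 0.75
#: (glutamate-limited: every glutamate becomes one protein precursor).
MINI_PHOTO_SGLM_OPTIMUM = 0.75
#: Max H2 at that optimum: 7*(1.57 - 0.75) - 4*0.75 e- pairs.
MINI_PHOTO_SGLM_MAX_H2 = 2.74
#: Max H2 at zero growth: (14*1.57 + 18*0.75)/2.
MINI_PHOTO_SGLM_MAX_H2_REST = 17.74

_BASE = {"EX_h2o": (-FREE, FREE), "EX_co2": (-FREE, FREE),
         "EX_so4": (-FREE, FREE)}


def medium_photo_sglm(sur: float = 1.57, glur: float = 0.75) -> Medium:
    """Anoxic light, succinate + glutamate at chemostat uptake rates."""
    return Medium("photo_succinate_glutamate",
                  {**_BASE, "EX_photon": (-FREE, 0.0),
                   "EX_suc": (-sur, FREE), "EX_glm": (-glur, FREE)},
                  notes="photoheterotrophic; light open, O2 closed")


def medium_photo_snh3(sur: float = 1.57, aur: float = 1.0) -> Medium:
    """Anoxic light, succinate + ammonia."""
    return Medium("photo_succinate_ammonia",
                  {**_BASE, "EX_photon": (-FREE, 0.0),
                   "EX_suc": (-sur, FREE), "EX_nh3": (-aur, FREE)},
                  notes="photoheterotrophic; light open, O2 closed")


def medium_aerobic_snh3(sur: float = 1.57, aur: float = 1.0) -> Medium:
    """Dark, O2 as electron acceptor, succinate + ammonia."""
    return Medium("aerobic_succinate_ammonia",
                  {**_BASE, "EX_o2": (-FREE, FREE),
                   "EX_suc": (-sur, FREE), "EX_nh3": (-aur, FREE)},
                  notes="dark aerobic respiration")


def medium_dark_dmso(sur: float = 1.57, aur: float = 1.0) -> Medium:
    """Dark anaerobic respiration with DMSO as electron acceptor."""
    return Medium("dark_dmso",
                  {**_BASE, "EX_dmso": (-FREE, FREE),
                   "EX_suc": (-sur, FREE), "EX_nh3": (-aur, FREE)},
                  notes="dark; DMSO reduced to DMS")


def medium_dark_no_acceptor(sur: float = 1.57, aur: float = 1.0) -> Medium:
    """Dark, no electron acceptor: fermentation is absent, so no growth."""
    return Medium("dark_no_acceptor",
                  {**_BASE, "EX_suc": (-sur, FREE), "EX_nh3": (-aur, FREE)},
                  notes="dark; no acceptor")


MEDIA_PRESETS = {
    "photo_sglm": medium_photo_sglm,
    "photo_snh3": medium_photo_snh3,
    "aerobic_snh3": medium_aerobic_snh3,
    "dark_dmso": medium_dark_dmso,
    "dark_none": medium_dark_no_acceptor,
}


# ---------------------------------------------------------------------------
# Random planted networks
# ---------------------------------------------------------------------------

@dataclass
class FixtureSpec:
    seed: int
    n_metabolites: int = 10
    n_reactions: int = 15
    parallel_sinks: bool = False
    sbc_loop: bool = False
    isozyme_gprs: bool = False
    maintenance: bool = False
    storage_demands: bool = False
    uptake: float = 10.0
    maintenance_flux: float = 1.0
    chain_length: int = 4  # metabolites on the planted pathway

    @property
    def planted_optimum(self) -> float:
        return self.uptake - (self.maintenance_flux if self.maintenance else 0.0)


def random_network(spec: FixtureSpec) -> MetabolicModel:
    """Connected network with a planted biomass route of known yield.

    The planted pathway is EX -> M0 -> ... -> M_{L-1} -> biomass with 1:1
    stoichiometry, so the optimum equals the uptake bound (minus the
    maintenance drain when enabled).  Decoy reactions divert planted
    intermediates into dead-end metabolites with no outlet, so they are
    blocked and cannot create a better optimum.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    m = MetabolicModel(f"random_net_{spec.seed}")
    m.compartments = {"c": "cytoplasm"}

    L = spec.chain_length
    core_mets = L + (1 if spec.parallel_sinks else 0) + (3 if spec.sbc_loop else 0)
    core_rxns = (
        L + 1  # exchange + chain + biomass
        + (3 if spec.parallel_sinks else 0)  # byproduct split + two sinks
        + (3 if spec.sbc_loop else 0)
        + (1 if spec.maintenance else 0)
        + (1 if spec.storage_demands else 0)
    )
    if spec.n_metabolites < core_mets or spec.n_reactions < core_rxns:
        raise ValueError(
            f"spec too small: needs >= {core_mets} metabolites and "
            f">= {core_rxns} reactions for the requested features"
        )

    for i in range(L):
        m.add_metabolite(Metabolite(f"M{i}", compartment="c"))
    m.add_reaction(Reaction("EX_M0", {"M0": -1.0}, -spec.uptake, FREE,
                            category="exchange"))
    for i in range(L - 1):
        gpr = None
        if spec.isozyme_gprs:
            if i == 0:
                gpr = "iso_g1 or iso_g2"
            elif i == 1:
                gpr = "cplx_g1 and cplx_g2"
        stoich = {f"M{i}": -1.0, f"M{i + 1}": 1.0}
        if spec.parallel_sinks and i == 0:
            if "B" not in m.metabolites:
                m.add_metabolite(Metabolite("B", compartment="c"))
            stoich["B"] = 1.0  # obligatory byproduct needing disposal
        m.add_reaction(Reaction(f"R{i}", stoich, 0.0, FREE, gpr))
    m.add_reaction(Reaction("BIOMASS", {f"M{L - 1}": -1.0}, 0.0, FREE,
                            category="biomass"))
    m.objective_reaction_id = "BIOMASS"

    if spec.parallel_sinks:
        m.add_reaction(Reaction("SINK_B_a", {"B": -1.0}, 0.0, FREE,
                                category="demand"))
        m.add_reaction(Reaction("SINK_B_b", {"B": -1.0}, 0.0, FREE,
                                category="demand"))
    if spec.sbc_loop:
        for i in range(3):
            m.add_metabolite(Metabolite(f"C{i}", compartment="c"))
        for i in range(3):
            m.add_reaction(
                Reaction(f"LOOP{i}", {f"C{i}": -1.0, f"C{(i + 1) % 3}": 1.0},
                         -FREE, FREE)
            )
    if spec.maintenance:
        m.add_reaction(Reaction("MAINT", {"M0": -1.0},
                                spec.maintenance_flux, spec.maintenance_flux,
                                category="demand"))
    if spec.storage_demands:
        m.add_reaction(Reaction("DM_storage", {"M1": -1.0}, 0.0, FREE,
                                category="demand"))

    # dead-end decoys up to the requested size
    n_dead = spec.n_metabolites - len(m.metabolites)
    for k in range(n_dead):
        m.add_metabolite(Metabolite(f"D{k}", compartment="c"))
    k = 0
    while len(m.reactions) < spec.n_reactions:
        if n_dead == 0:
            raise ValueError("cannot pad reactions without decoy metabolites")
        src = f"M{rng.integers(0, L)}"
        dst = f"D{rng.integers(0, n_dead)}"
        coeff = float(rng.integers(1, 3))
        m.add_reaction(Reaction(f"DECOY{k}", {src: -1.0, dst: coeff}, 0.0, FREE))
        k += 1
    return m


# ---------------------------------------------------------------------------
# Synthetic chemostat measurements
# ---------------------------------------------------------------------------

def chemostat_measurements(
    model: MetabolicModel,
    medium: Medium,
    noise_sd: float = 0.05,
    n_replicates: int = 1,
    seed: int = 0,
    dw_true: float = 100.0,
    phb_mass_true: float = 10.0,
    glycogen_mass_true: float = 2.0,
    theta: float = THETA_PHOTO,
):
    """Emulate steady-state chemostat outputs for a solved fixture.

    Solves FBA under ``medium`` and reports, per replicate, the uptake and
    secretion fluxes plus a COD/storage-polymer mass set consistent with
    ``dw_true`` mg of cells.  Relative Gaussian noise of ``noise_sd`` is
    applied to every measurement; ``noise_sd=0`` returns the exact truth.
    Returns ``(DataFrame, truth)`` where ``truth`` holds the noiseless
    values for recovery tests.
    """
    rng = np.random.default_rng(seed)
    dist = fba(model, medium)
    if not dist.optimal:
        raise RuntimeError(f"fixture FBA is {dist.status}")
    flux_cols = {
        f"flux_{rid}": v for rid, v in dist.fluxes.items()
        if model.reactions[rid].is_boundary() and abs(v) > ZERO_FLUX_TOL
    }
    cod_true = (theta * dw_true + COD_PER_MG_PHB * phb_mass_true
                + COD_PER_MG_GLYCOGEN * glycogen_mass_true)
    truth = {
        "dw_mg": dw_true, "phb_mg": phb_mass_true,
        "glycogen_mg": glycogen_mass_true, "cod_biomass_mg": cod_true,
        "theta": theta, "growth_rate": dist.objective_value,
        **flux_cols,
    }
    rows = []
    for _ in range(n_replicates):
        def jitter(x):
            return x * (1.0 + noise_sd * rng.standard_normal()) if noise_sd > 0 else x

        row = {
            "cod_biomass_mg": jitter(cod_true),
            "phb_mg": jitter(phb_mass_true),
            "glycogen_mg": jitter(glycogen_mass_true),
            "theta": theta,
        }
        for cname, v in flux_cols.items():
            row[cname] = jitter(v)
        rows.append(row)
    return pd.DataFrame(rows), truth
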