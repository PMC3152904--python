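"""Biomass objective formulation and COD-based dry-weight normalization.

The biomass objective function (BOF) is a pseudo-reaction draining monomer
precursors in the proportions measured for 1 g of dry cells: for a
macromolecule with mass fraction f (g/gDW) and a monomer contributing mass
fraction m of that macromolecule with molecular weight MW (g/mol),

    coefficient = 1000 * f * m / MW     [mmol precursor / gDW]

plus polymerization water release (one condensation per monomer of a
polymeric class) and the growth-associated maintenance (GAM) ATP
hydrolysis.  Storage polymers (PHB, glycogen) vary strongly with condition
and are excluded from the BOF — they accumulate through demand reactions
instead — and the remaining fractions, plus the unassigned residue treated
as ash, are renormalized so the drained precursors represent 1 g.

Dry weight from chemical oxygen demand (COD) measurements subtracts the
storage-polymer COD before converting at the cell-mass COD/weight ratio θ:

    dW = (COD_biomass - 1.67 * m_PHB - 1.18 * m_glycogen) / θ

with θ = 1.62 (photosynthetic) or 1.56 (aerobic) mgCOD/mg, or θ computed
from the BOF's own electron content at 8 gCOD per electron-mole.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._formula import GRAMS_COD_PER_EMOL, degree_of_reduction, molecular_weight
from .model_core import Reaction

COD_PER_MG_PHB = 1.67  # mgCOD/mg
COD_PER_MG_GLYCOGEN = 1.18  # mgCOD/mg
THETA_PHOTO = 1.62  # mgCOD/mg cell mass, photosynthetic cultures
THETA_AERO = 1.56  # mgCOD/mg cell mass, aerobic cultures
DEFAULT_GAM = 40.0  # mmol ATP/gDW; estimation method is external, value is a knob
STORAGE_POLYMERS = ("PHB", "Glycogen")

ASH_PSEUDO_MW = 100.0  # g/mol bookkeeping weight for the inert ash drain


@dataclass
class BiomassComposition:
    """Macromolecule mass fractions in g/gDW for one growth condition."""

    fractions: dict[str, float]
    condition: str = ""

    def __post_init__(self):
        for k, v in self.fractions.items():
            if v < 0:
                raise ValueError(f"negative mass fraction for {k!r}")
        if sum(self.fractions.values()) > 1.0 + 1e-9:
            raise ValueError("mass fractions sum to more than 1 g/gDW")

    @property
    def ash_fraction(self) -> float:
        """Unassigned residue, reported as inorganic/ash."""
        return max(0.0, 1.0 - sum(self.fractions.values()))


# Measured macromolecular composition of photoheterotrophically and
# aerobically grown cells (g per g dry weight).
PHOTO_COMPOSITION = BiomassComposition(
    {
        "DNA": 0.019, "RNA": 0.051, "Protein": 0.536, "Lipids": 0.171,
        "PHB": 0.104, "Bacteriochlorophyll": 0.004, "Carotenoids": 0.001,
        "Glycogen": 0.014, "LPS": 0.030, "CellWall": 0.020,
    },
    condition="photoheterotrophic",
)
AERO_COMPOSITION = BiomassComposition(
    {
        "DNA": 0.028, "RNA": 0.071, "Protein": 0.493, "Lipids": 0.128,
        "PHB": 0.176, "Bacteriochlorophyll": 0.0, "Carotenoids": 0.0,
        "Glycogen": 0.004, "LPS": 0.030, "CellWall": 0.020,
    },
    condition="aerobic",
)


@dataclass
class Monomer:
    id: str
    mass_fraction: float  # of the parent macromolecule
    formula: str | None = None
    mw: float | None = None  # g/mol; derived from the formula when omitted

    def molecular_weight(self) -> float:
        if self.mw is not None:
            return self.mw
        if self.formula:
            return molecular_weight(self.formula)
        raise ValueError(f"monomer {self.id!r} has neither MW nor formula")


@dataclass
class MacromoleculeProfile:
    monomers: list[Monomer]
    polymeric: bool = True  # condensation polymer: releases 1 water/monomer

    def __post_init__(self):
        total = sum(m.mass_fraction for m in self.monomers)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"monomer mass fractions sum to {total:.6f}, expected 1"
            )


MonomerProfile = dict[str, MacromoleculeProfile]


def _normalized(pairs: list[tuple[str, float, str]]) -> list[Monomer]:
    total = sum(w for _, w, _ in pairs)
    return [Monomer(i, w / total, f) for i, w, f in pairs]


# Generic bacterial amino-acid usage (mass weights, normalized below) with
# free-monomer formulas; a coarse stand-in for proteome-derived statistics.
_AMINO_ACIDS = _normalized([
    ("ala", 0.096, "C3H7NO2"), ("arg", 0.055, "C6H14N4O2"),
    ("asn", 0.045, "C4H8N2O3"), ("asp", 0.045, "C4H7NO4"),
    ("cys", 0.017, "C3H7NO2S"), ("gln", 0.050, "C5H10N2O3"),
    ("glu", 0.050, "C5H9NO4"), ("gly", 0.078, "C2H5NO2"),
    ("his", 0.018, "C6H9N3O2"), ("ile", 0.054, "C6H13NO2"),
    ("leu", 0.084, "C6H13NO2"), ("lys", 0.064, "C6H14N2O2"),
    ("met", 0.029, "C5H11NO2S"), ("phe", 0.035, "C9H11NO2"),
    ("pro", 0.041, "C5H9NO2"), ("ser", 0.040, "C3H7NO3"),
    ("thr", 0.047, "C4H9NO3"), ("trp", 0.011, "C11H12N2O2"),
    ("tyr", 0.026, "C9H11NO3"), ("val", 0.059, "C5H11NO2"),
])


def nucleotide_profile(gc: float, deoxy: bool = False) -> list[Monomer]:
    """Nucleoside-monophosphate mass fractions from genomic GC content."""
    if not 0 < gc < 1:
        raise ValueError("GC content must be in (0, 1)")
    if deoxy:
        species = [("damp", "C10H14N5O6P"), ("dtmp", "C10H15N2O8P"),
                   ("dgmp", "C10H14N5O7P"), ("dcmp", "C9H14N3O7P")]
    else:
        species = [("amp", "C10H14N5O7P"), ("ump", "C9H13N2O9P"),
                   ("gmp", "C10H14N5O8P"), ("cmp", "C9H14N3O8P")]
    moles = [(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2]
    weights = [(i, x * molecular_weight(f), f) for (i, f), x in zip(species, moles)]
    return _normalized(weights)


def default_monomer_profile(gc: float = 0.69) -> MonomerProfile:
    """Bundled default monomer profile (GC defaults to the organism's ~69%).

    Lipid, lipopolysaccharide and cell-wall species are single
    representative compounds from the literature rather than full lipidomes.
    """
    return {
        "Protein": MacromoleculeProfile(list(_AMINO_ACIDS)),
        "RNA": MacromoleculeProfile(nucleotide_profile(gc)),
        "DNA": MacromoleculeProfile(nucleotide_profile(gc, deoxy=True)),
        "Lipids": MacromoleculeProfile(
            [Monomer("phosphatidylethanolamine", 1.0, "C39H76NO8P")],
            polymeric=False,
        ),
        "Bacteriochlorophyll": MacromoleculeProfile(
            [Monomer("bchl_a", 1.0, "C55H74MgN4O6")], polymeric=False
        ),
        "Carotenoids": MacromoleculeProfile(
            [Monomer("spheroidene", 1.0, "C41H60O")], polymeric=False
        ),
        "LPS": MacromoleculeProfile([Monomer("lps_unit", 1.0, "C35H62N2O22")]),
        "CellWall": MacromoleculeProfile(
            [Monomer("peptidoglycan_unit", 1.0, "C37H60N8O20")]
        ),
        "PHB": MacromoleculeProfile([Monomer("hydroxybutyrate", 1.0, "C4H8O3")]),
        "Glycogen": MacromoleculeProfile([Monomer("glucose", 1.0, "C6H12O6")]),
    }


@dataclass
class BofResult:
    reaction: Reaction
    table: pd.DataFrame  # per-precursor coefficient, MW, formula, mass
    represented_mass: float  # g precursor per gDW drained (target: 1)
    ash_fraction: float
    gam: float


def formulate_bof(
    composition: BiomassComposition,
    monomers: MonomerProfile | None = None,
    gam: float = DEFAULT_GAM,
    exclude: tuple[str, ...] = STORAGE_POLYMERS,
    renormalize: bool = True,
    reaction_id: str = "BIOMASS",
) -> BofResult:
    """Build the biomass pseudo-reaction from measured composition.

    With ``renormalize`` (default), the excluded storage polymers are
    removed and the remaining fractions plus ash are rescaled so the drained
    precursors represent exactly 1 g; with ``renormalize=False`` the raw
    fractions are used as given (coefficients are then linear in the
    fractions).
    """
    monomers = monomers if monomers is not None else default_monomer_profile()
    included = {
        k: v for k, v in composition.fractions.items() if k not in exclude
    }
    for k in included:
        if k not in monomers and included[k] > 0:
            raise KeyError(f"no monomer profile for macromolecule {k!r}")
    ash = composition.ash_fraction
    if renormalize:
        denom = sum(included.values()) + ash
        if denom <= 0:
            raise ValueError("nothing left in the biomass composition")
        scale = 1.0 / denom
    else:
        scale = 1.0

    rows = []
    stoich: dict[str, float] = {}
    water_released = 0.0
    for macro, fraction in included.items():
        if fraction == 0:
            continue
        profile = monomers[macro]
        for mon in profile.monomers:
            mw = mon.molecular_weight()
            coeff = 1000.0 * (fraction * scale) * mon.mass_fraction / mw
            stoich[mon.id] = stoich.get(mon.id, 0.0) - coeff
            if profile.polymeric:
                water_released += coeff
            rows.append({
                "macromolecule": macro, "precursor": mon.id,
                "coefficient_mmol_per_gDW": coeff, "mw": mw,
                "formula": mon.formula,
                "mass_g": coeff * mw / 1000.0,
            })
    if ash > 0:
        coeff = 1000.0 * (ash * scale) / ASH_PSEUDO_MW
        stoich["ash"] = stoich.get("ash", 0.0) - coeff
        rows.append({
            "macromolecule": "Ash", "precursor": "ash",
            "coefficient_mmol_per_gDW": coeff, "mw": ASH_PSEUDO_MW,
            "formula": None, "mass_g": ash * scale,
        })

    # energy and water bookkeeping: GAM hydrolysis plus condensation water
    stoich["atp"] = stoich.get("atp", 0.0) - gam
    stoich["h2o"] = stoich.get("h2o", 0.0) - gam + water_released
    stoich["adp"] = stoich.get("adp", 0.0) + gam
    stoich["pi"] = stoich.get("pi", 0.0) + gam

    table = pd.DataFrame(rows)
    represented = float(table["mass_g"].sum()) if len(rows) else 0.0
    reaction = Reaction(
        id=reaction_id,
        stoichiometry={k: v for k, v in stoich.items() if v != 0.0},
        lower_bound=0.0,
        upper_bound=1000.0,
        category="biomass",
        name=f"biomass ({composition.condition})" if composition.condition else "biomass",
    )
    return BofResult(reaction, table, represented, ash * scale, gam)


# ---------------------------------------------------------------------------
# COD dry weight
# ---------------------------------------------------------------------------

@dataclass
class CodSample:
    cod_biomass: float  # mgCOD in the sample
    phb_mass: float = 0.0  # mg
    glycogen_mass: float = 0.0  # mg
    theta: float = THETA_PHOTO  # mgCOD/mg cell mass


def cod_dry_weight(sample: CodSample) -> float:
    """Net cell dry weight (mg) from a COD mass balance, storage polymers
    subtracted at their theoretical COD/weight ratios."""
    net_cod = (
        sample.cod_biomass
        - COD_PER_MG_PHB * sample.phb_mass
        - COD_PER_MG_GLYCOGEN * sample.glycogen_mass
    )
    if net_cod <= 0:
        raise ValueError(
            "storage-polymer COD exceeds total biomass COD; measurements inconsistent"
        )
    return net_cod / sample.theta


def cod_per_gram(formula: str, charge: int = 0) -> float:
    """gCOD per g of a compound: 8 gCOD/e-mol times electrons per gram."""
    gamma = degree_of_reduction(formula, charge)
    return GRAMS_COD_PER_EMOL * max(gamma, 0.0) / molecular_weight(formula)


def theta_from_bof(bof: BofResult) -> float:
    """COD/weight ratio θ (gCOD/g) of the 1 g precursor bundle a BOF drains.

    Requires an elemental formula for every mass-carrying precursor except
    the inert ash pseudo-component (which contributes zero electrons).
    """
    total_emol = 0.0
    for row in bof.table.itertuples():
        if row.precursor == "ash":
            continue
        if not row.formula:
            raise ValueError(f"precursor {row.precursor!r} lacks a formula")
        gamma = degree_of_reduction(row.formula)
        total_emol += (row.coefficient_mmol_per_gDW / 1000.0) * max(gamma, 0.0)
    return GRAMS_COD_PER_EMOL * total_emol / max(bof.represented_mass, 1e-12)
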