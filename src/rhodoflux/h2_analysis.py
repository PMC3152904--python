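"""H2 production envelopes, electron-balance accounting and competing sinks.

During anoxic phototrophic growth, nitrogenase-driven H2 production is one
of several sinks for excess substrate reducing power; the production
envelope (max/min H2 flux as a function of fixed biomass flux) and an
electron ledger built from half-reaction degree-of-reduction counts make
the competition quantitative.  Substrate and product fluxes convert to
electron fluxes via gamma (e-/mol); the fitted line of H2 electron outflow
versus substrate electron inflow has slope 1 exactly when every electron
not consumed by growth can reach H2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._formula import degree_of_reduction
from .lp_engine import ZERO_FLUX_TOL, fba
from .model_core import MetabolicModel

H2_ELECTRONS = 2.0  # e- per mol H2 (H2 -> 2 H+ + 2 e-)


def electron_equivalents(formula: str, charge: int = 0) -> float:
    """Available electrons per mole (degree of reduction), ammonia-reference
    convention for nitrogen."""
    return degree_of_reduction(formula, charge)


@dataclass
class EnvelopePoint:
    biomass_flux: float
    min_flux: float | None
    max_flux: float | None
    feasible: bool = True


def production_envelope(
    model: MetabolicModel,
    medium=None,
    target_id: str = "",
    objective_id: str | None = None,
    n_points: int = 101,
) -> pd.DataFrame:
    """Max/min target flux on a grid of fixed biomass fluxes over [0, Z].

    The envelope of an LP projection is concave in the biomass flux over the
    feasible interval; the grid point at Z reproduces the FVA max of the
    target at fixed optimum.
    """
    objective_id = objective_id or model.objective_reaction_id
    if target_id not in model.reactions:
        raise KeyError(f"target reaction {target_id!r} not in model")
    wt = fba(model, medium, objective_id)
    if not wt.optimal:
        raise RuntimeError(f"FBA under the given medium is {wt.status}")
    Z = wt.objective_value
    rows = []
    for b in np.linspace(0.0, Z, n_points):
        overrides = dict(medium.bounds) if hasattr(medium, "bounds") else dict(medium or {})
        overrides[objective_id] = (b, b)
        lo = fba(model, overrides, target_id, sense="min")
        hi = fba(model, overrides, target_id, sense="max")
        if lo.optimal and hi.optimal:
            rows.append({"biomass_flux": b, "min_flux": lo.objective_value,
                         "max_flux": hi.objective_value, "feasible": True})
        else:
            rows.append({"biomass_flux": b, "min_flux": np.nan,
                         "max_flux": np.nan, "feasible": False})
    return pd.DataFrame(rows)


def envelope_peak(envelope: pd.DataFrame) -> tuple[float, float]:
    """(biomass flux, max target flux) at the envelope's maximum point."""
    ok = envelope[envelope["feasible"]]
    i = ok["max_flux"].idxmax()
    return float(ok.loc[i, "biomass_flux"]), float(ok.loc[i, "max_flux"])


# ---------------------------------------------------------------------------
# Electron ledger
# ---------------------------------------------------------------------------

@dataclass
class ElectronLedger:
    inflow: dict[str, float] = field(default_factory=dict)  # e- mmol/gDW/h by reaction
    outflow: dict[str, float] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)  # boundary mets without formula

    @property
    def total_in(self) -> float:
        return sum(self.inflow.values())

    @property
    def total_out(self) -> float:
        return sum(self.outflow.values())

    @property
    def residual(self) -> float:
        return self.total_in - self.total_out


def electron_ledger(model: MetabolicModel, dist, biomass_id: str | None = None) -> ElectronLedger:
    """Electron flows across every boundary reaction plus the biomass drain.

    Uptake (negative exchange flux) of a compound with gamma > 0 is inflow;
    secretion/accumulation is outflow.  The biomass reaction's reactant
    electrons count as outflow into cell material.  Metabolites without a
    formula contribute zero and are listed in ``skipped``.
    """
    biomass_id = biomass_id or model.objective_reaction_id
    ledger = ElectronLedger()
    for rid, rxn in model.reactions.items():
        v = dist.fluxes.get(rid, 0.0)
        if abs(v) <= ZERO_FLUX_TOL:
            continue
        if rxn.is_boundary():
            (mid,) = rxn.stoichiometry
            met = model.metabolites[mid]
            if not met.formula:
                ledger.skipped.append(mid)
                continue
            gamma = degree_of_reduction(met.formula, met.charge or 0)
            flow = -rxn.stoichiometry[mid] * v * gamma  # + = leaving the cell
            if flow >= 0:
                ledger.outflow[rid] = ledger.outflow.get(rid, 0.0) + flow
            else:
                ledger.inflow[rid] = ledger.inflow.get(rid, 0.0) - flow
        elif rid == biomass_id:
            e = 0.0
            for mid, coeff in rxn.stoichiometry.items():
                met = model.metabolites[mid]
                if not met.formula:
                    if mid not in ledger.skipped:
                        ledger.skipped.append(mid)
                    continue
                e -= coeff * degree_of_reduction(met.formula, met.charge or 0)
            ledger.outflow[rid] = e * v
    return ledger


def electron_balance_fit(substrate_e, h2_e) -> tuple[float, float, float]:
    """Least-squares line of H2 electron flux vs substrate electron flux.

    Returns (slope, intercept, r^2).  Raises on a degenerate x-range (two
    identical runs cannot anchor a line).
    """
    x = np.asarray(substrate_e, dtype=float)
    y = np.asarray(h2_e, dtype=float)
    if x.size < 2 or np.ptp(x) < 1e-9:
        raise ValueError("degenerate substrate-electron range; need >= 2 distinct runs")
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


# ---------------------------------------------------------------------------
# Competing electron sinks
# ---------------------------------------------------------------------------

@dataclass
class SinkStep:
    reaction: str
    gain: float  # increase in max target flux when this sink is eliminated
    cumulative_max: float


@dataclass
class SinkReport:
    baseline_max: float
    steps: list[SinkStep] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)  # growth-infeasible knockouts

    @property
    def final_max(self) -> float:
        return self.steps[-1].cumulative_max if self.steps else self.baseline_max

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"reaction": s.reaction, "gain": s.gain,
              "cumulative_max": s.cumulative_max} for s in self.steps]
        )


def default_sink_candidates(model: MetabolicModel, target_id: str) -> list[str]:
    """Boundary reactions whose metabolite carries electrons (reduced
    secreted/stored products), excluding the target itself."""
    out = []
    for rid in model.boundary_reactions():
        if rid == target_id:
            continue
        (mid,) = model.reactions[rid].stoichiometry
        met = model.metabolites[mid]
        if met.formula and degree_of_reduction(met.formula, met.charge or 0) > 0:
            out.append(rid)
    return out


def competing_sinks(
    model: MetabolicModel,
    medium=None,
    target_id: str = "",
    objective_id: str | None = None,
    candidates: list[str] | None = None,
    gain_tol: float = 1e-6,
) -> SinkReport:
    """Greedy elimination of electron sinks competing with the target.

    At the optimal growth rate, repeatedly knock out the candidate whose
    removal most increases the max target flux; stop when no candidate
    yields a gain.  Candidates whose removal makes growth infeasible are
    skipped and flagged.  The cumulative max is non-decreasing by
    construction.
    """
    objective_id = objective_id or model.objective_reaction_id
    if candidates is None:
        candidates = default_sink_candidates(model, target_id)

    def max_target(knocked) -> float | None:
        """Max target flux at the growth optimum with ``knocked`` sinks shut,
        or None if growth itself becomes infeasible."""
        overrides = dict(medium.bounds) if hasattr(medium, "bounds") else dict(medium or {})
        for rid in knocked:
            overrides[rid] = (0.0, 0.0)
        wt = fba(model, overrides, objective_id)
        if not wt.optimal or wt.objective_value <= ZERO_FLUX_TOL:
            return None
        Z = wt.objective_value
        slack = 1e-6 * max(1.0, abs(Z))
        rxn = model.reactions[objective_id]
        overrides[objective_id] = (Z - slack, min(rxn.upper_bound, Z + slack))
        hi = fba(model, overrides, target_id, sense="max")
        return hi.objective_value if hi.optimal else None

    eliminated: list[str] = []
    report = None
    baseline = max_target(())
    if baseline is None:
        raise RuntimeError("growth is infeasible under the baseline medium")
    report = SinkReport(baseline_max=baseline)
    remaining = list(candidates)
    current = baseline
    while remaining:
        best = None
        values = {c: max_target(tuple(eliminated + [c])) for c in remaining}
        for c in [c for c, v in values.items() if v is None]:
            remaining.remove(c)
            if c not in report.skipped:
                report.skipped.append(c)
        for cand, val in values.items():
            if val is None:
                continue
            if best is None or val > best[1]:
                best = (cand, val)
        if best is None or best[1] <= current + gain_tol:
            break
        cand, val = best
        eliminated.append(cand)
        remaining.remove(cand)
        report.steps.append(SinkStep(cand, val - current, val))
        current = val
    return report
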