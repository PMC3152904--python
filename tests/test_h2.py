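"""Production envelopes, electron accounting and competing-sink analysis."""

import numpy as np
import pytest

from rhodoflux import (
    competing_sinks,
    electron_balance_fit,
    electron_equivalents,
    electron_ledger,
    envelope_peak,
    fba,
    fva,
    production_envelope,
)
from rhodoflux.synthetic_data import (
    MINI_PHOTO_SGLM_MAX_H2,
    MINI_PHOTO_SGLM_MAX_H2_REST,
    MINI_PHOTO_SGLM_OPTIMUM,
)


@pytest.mark.parametrize(
    "formula, charge, expected",
    [
        ("C4H6O4", 0, 14.0),   # succinate
        ("H2", 0, 2.0),        # H2 -> 2 H+ + 2 e-
        ("C5H9NO4", 0, 18.0),  # glutamate (ammonia convention for N)
        ("CO2", 0, 0.0),
        ("H2S", 0, 8.0),       # sulfate reference for S
        ("O4S", -2, 0.0),      # sulfate itself
    ],
)
def test_electron_equivalents(formula, charge, expected):
    assert electron_equivalents(formula, charge) == expected


def test_electron_equivalents_unknown_element():
    with pytest.raises(ValueError):
        electron_equivalents("C2U3")


def test_envelope_shape_and_endpoints(mini, photo_sglm):
    env = production_envelope(mini, photo_sglm, "EX_h2", n_points=21)
    assert env.feasible.all()
    # endpoint checks against the planted values
    assert env.iloc[0].max_flux == pytest.approx(MINI_PHOTO_SGLM_MAX_H2_REST, abs=1e-4)
    assert env.iloc[-1].max_flux == pytest.approx(MINI_PHOTO_SGLM_MAX_H2, abs=1e-3)
    # concavity of the LP projection: second differences non-positive
    y = env.max_flux.to_numpy()
    d2 = np.diff(y, 2)
    assert np.all(d2 <= 1e-6)


def test_envelope_max_at_optimum_equals_fva(mini, photo_sglm):
    env = production_envelope(mini, photo_sglm, "EX_h2", n_points=5)
    at_opt = env.iloc[-1].max_flux
    ranges = fva(mini, photo_sglm, reactions=["EX_h2"]).ranges["EX_h2"]
    assert at_opt == pytest.approx(ranges[1], abs=1e-3)


def test_envelope_zero_capacity_target(mini, photo_sglm):
    """DMS secretion requires DMSO uptake, closed in this medium: the whole
    envelope is identically zero."""
    env = production_envelope(mini, photo_sglm, "EX_dms", n_points=5)
    assert np.allclose(env.max_flux, 0.0, atol=1e-8)
    assert np.allclose(env.min_flux, 0.0, atol=1e-8)


def test_resting_cells_h2_equals_substrate_electrons(mini, photo_sglm):
    """At zero growth all substrate reducing power can leave as H2:
    (14*1.57 + 18*0.75) / 2 per the half-reaction stoichiometry."""
    overrides = dict(photo_sglm.bounds)
    overrides["BIOMASS"] = (0.0, 0.0)
    hi = fba(mini, overrides, "EX_h2", sense="max")
    expected = (14 * 1.57 + 18 * 0.75) / 2
    assert hi.objective_value == pytest.approx(expected, abs=1e-9)


def test_electron_ledger_closes(mini, photo_sglm):
    dist = fba(mini, photo_sglm)
    ledger = electron_ledger(mini, dist)
    assert ledger.residual == pytest.approx(0.0, abs=1e-8)
    assert ledger.total_in == pytest.approx(14 * 1.57 + 18 * 0.75, abs=1e-8)


def test_electron_fit_slope_one_with_sole_sink(mini, photo_sglm):
    """H2 as the only non-biomass electron sink at fixed growth: slope is
    exactly 1 and the intercept is minus the growth electron demand."""
    mu = 0.3
    closed_sinks = {"DM_phb": (0.0, 0.0), "DM_glyc": (0.0, 0.0),
                    "EX_h2s": (0.0, 0.0), "BIOMASS": (mu, mu),
                    "EX_glm": (-mu, 1000.0)}
    xs, ys = [], []
    for sur in [0.8, 1.0, 1.2, 1.4, 1.57]:
        overrides = dict(photo_sglm.bounds)
        overrides.update(closed_sinks)
        overrides["EX_suc"] = (-sur, 1000.0)
        hi = fba(mini, overrides, "EX_h2", sense="max")
        assert hi.optimal
        xs.append(14 * sur + 18 * mu)
        ys.append(2 * hi.objective_value)
    slope, intercept, r2 = electron_balance_fit(xs, ys)
    assert slope == pytest.approx(1.0, abs=1e-6)
    # biomass drains 18 + 22 = 40 e- per unit flux
    assert intercept == pytest.approx(-40 * mu, abs=1e-6)
    assert r2 == pytest.approx(1.0, abs=1e-9)


def test_electron_fit_degenerate_runs_rejected():
    with pytest.raises(ValueError):
        electron_balance_fit([5.0, 5.0], [1.0, 1.0])


def test_competing_sinks_forced_storage(mini, photo_sglm):
    """Forcing PHB and H2S production at a fixed growth rate diverts their
    electron capacity from H2; greedy elimination recovers exactly
    capacity/2 per sink (PHB unit: 18 e- -> 9 H2; H2S: 8 e- -> 4 H2).
    Biomass is pinned so the growth optimum cannot shift between steps."""
    forced = photo_sglm.updated({"DM_phb": (1.0, 1.0), "EX_h2s": (1.0, 1000.0),
                                 "BIOMASS": (0.2, 0.2)})
    report = competing_sinks(mini, forced, target_id="EX_h2",
                             candidates=["DM_phb", "EX_h2s"])
    gains = {s.reaction: s.gain for s in report.steps}
    assert gains["DM_phb"] == pytest.approx(9.0, abs=1e-3)
    assert gains["EX_h2s"] == pytest.approx(4.0, abs=1e-3)
    assert report.final_max == pytest.approx(report.baseline_max + 13.0, abs=1e-3)
    # cumulative max is non-decreasing
    cums = [report.baseline_max] + [s.cumulative_max for s in report.steps]
    assert all(b >= a - 1e-9 for a, b in zip(cums, cums[1:]))


def test_competing_sinks_no_candidates(mini, photo_sglm):
    report = competing_sinks(mini, photo_sglm, target_id="EX_h2", candidates=[])
    assert report.steps == []
    assert report.final_max == report.baseline_max


def test_envelope_peak_helper(mini, photo_sglm):
    env = production_envelope(mini, photo_sglm, "EX_h2", n_points=11)
    b, v = envelope_peak(env)
    assert v == env.max_flux.max()
    assert 0.0 <= b <= MINI_PHOTO_SGLM_OPTIMUM
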