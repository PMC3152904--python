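# rhodoflux

Constraint-based analysis of phototrophic metabolic networks, built around
the workflows used to interrogate genome-scale models of purple non-sulfur
bacteria such as *Rhodobacter sphaeroides*: flux balance analysis (FBA),
flux variability analysis (FVA), mixed-integer enumeration of alternate
optima, reaction/gene essentiality with boolean gene–protein–reaction (GPR)
rules, biomass-objective formulation from measured cell composition,
COD-based dry-weight normalization, and hydrogen production-envelope /
electron-balance analysis. It is aimed at researchers studying
photofermentative H2 production and redox balancing in facultative
phototrophs.

## The core computations

**FBA** maximizes the flux through a biomass objective `v_bio` subject to
steady-state mass balance and flux bounds:

```
max  v_bio
s.t. S v = 0,    v_min <= v <= v_max
```

with `S` the stoichiometric matrix (metabolites x reactions), bounds at the
±1000 mmol/gDW/h box for reversible reactions, 0/1000 for irreversible
ones, and exchange reactions written as `metabolite_e ->` so negative flux
is uptake. **FVA** fixes `v_bio` at the FBA optimum `Z` and
minimizes/maximizes each reaction flux in turn. **Alternate optima** are
enumerated over designated "fluxes of interest" `v_i` (redox sinks) with
binaries `y_i + w_i = 1`, big-M bound collapse `lb_i w_i <= v_i <= ub_i
w_i`, and one integer cut `sum_{i in NZ_j} y_i >= 1` per previously found
nonzero-support set `NZ_j`, so no support pattern is revisited.

The **biomass objective** drains monomer precursors at `1000 * f * m / MW`
mmol/gDW (macromolecule mass fraction `f`, monomer mass fraction `m`,
molecular weight `MW`), excluding the condition-dependent storage polymers
PHB and glycogen, which accumulate through demand reactions instead.
Dry weight follows a chemical-oxygen-demand balance
`dW = (COD_biomass - 1.67 m_PHB - 1.18 m_glycogen) / theta`, and electron
accounting uses half-reaction degrees of reduction
(`gamma = 4C + H - 2O - 3N + 6S + 5P - charge`; succinate 14 e-/mol, H2 2
e-/mol, 8 gCOD per electron-mole).

Everything is exercised on bundled synthetic networks — chiefly a
hand-audited ~45-reaction "mini-phototroph" with a cyclic photosynthetic
electron transport chain, a reversible NADH dehydrogenase, nitrogenase H2
output and PHB/H2S/glycogen sinks — whose LP optima and electron ledgers
are known in closed form. An external SBML model (Level 3 + fbc, or the
legacy Level 2 COBRA dialect) can be substituted anywhere via `read_sbml`.

## Worked example

```python
import rhodoflux as rf
from rhodoflux.synthetic_data import medium_photo_sglm

model = rf.mini_phototroph()
medium = medium_photo_sglm()          # anoxic light, succinate 1.57 + glutamate 0.75

dist = rf.fba(model, medium)
print(dist.objective_value)           # 0.75  (growth rate, 1/h; nitrogen-limited)

env = rf.production_envelope(model, medium, "EX_h2", n_points=21)
print(env.iloc[-1].max_flux)          # 2.7400  (max H2 at optimal growth, mmol/gDW/h)
print(env.iloc[0].max_flux)           # 17.74   (max H2 for resting cells)

ledger = rf.electron_ledger(model, dist)
print(ledger.total_in, ledger.residual)   # 35.48  0.0   (14*1.57 + 18*0.75 e-, closed)
```

Growth is glutamate-limited (every glutamate becomes one protein
precursor), so the optimum is 0.75 1/h. At that optimum the network can
still export 2.74 mmol H2/gDW/h — exactly the reducing power of the surplus
succinate minus the lipid demand, `7*(1.57-0.75) - 4*0.75` NADH pairs — and
resting cells can convert the entire substrate electron inflow (35.48
e- mmol/gDW/h) to H2. With chemostat-style fixed uptakes the alternate-
optima enumeration finds the four equivalent single-sink optima (H2, H2S,
PHB, glycogen) and terminates with an infeasibility certificate.

A command-line interface mirrors the library
(`rhodoflux synth|summary|simulate|fva|altopt|essentiality|classify|screen|
envelope|electrons|sinks|bof|dryweight|loops`); each run writes TSV/JSON
artifacts plus a reproducibility manifest.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the whole pipeline from scratch on the synthetic fixtures — growth
simulation, FVA, blocked/cycle detection, alternate-optima enumeration,
essentiality screens, classification, substrate screening, biomass
formulation with mass closure, noisy COD dry-weight recovery, the H2
envelope and the electron-balance fit — logging each stage's numbers to
stderr and writing the result JSON to `--out`. The `--seed` argument
controls all randomness (fixture generation and measurement noise).
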