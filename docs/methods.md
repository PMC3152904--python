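# Methods

This note records the models implemented in `rhodoflux`, their assumptions,
the numerical choices behind them, and what the synthetic fixtures do and
do not establish.

## Constraint-based core

The network is a stoichiometric matrix `S` (metabolites x reactions) with
box bounds: ±1000 mmol/gDW/h for reversible reactions, [0, 1000] for
forward-only, [-1000, 0] for backward-only. Exchange reactions are written
`metabolite_e ->`, so positive flux is secretion and negative flux is
uptake; by default exchanges allow secretion only, and a `Medium` opens the
lower bound to minus the uptake rate for supplied components (or to the
-1000 box for freely exchanged species such as water and CO2). A fixed
non-growth ATP maintenance flux belongs in the model (the genome-scale
convention is 8.39 mmol ATP/gDW/h; the mini fixture uses 0.5 at its smaller
scale).

FBA maximizes the biomass flux with HiGHS (`scipy.optimize.linprog`). A
single solver-chosen optimal vertex is returned; no canonicalization is
attempted, because degeneracy is handled explicitly by the enumeration
module. Unbounded objectives are reported as such — they signal a missing
constraint or a balanced cycle feeding the objective.

Numerical conventions, used consistently everywhere:

* feasibility tolerance 1e-9 (bounds), steady-state residual checked at
  1e-6 (scaled);
* "zero flux" threshold 1e-6 mmol/gDW/h for blocked/active/essential
  classification. No source specifies this cutoff; it is the sensitivity
  knob behind any active/inactive partition and is exposed as
  `lp_engine.ZERO_FLUX_TOL`;
* objective fixing in FVA and in the MILP uses a relative band/floor of
  1e-6 around the optimum `Z` rather than strict equality, which is
  numerically brittle;
* growth threshold 1e-6 1/h separates growth from solver noise.

Blocked-reaction detection runs FVA with no objective fixed in the "fully
open system" (every exchange at the ±1000 box, demands relaxed). Balanced-
cycle (SBC) detection closes every boundary reaction, relaxes any forced
internal flux (e.g. the fixed maintenance), and flags reactions with a
nonzero FVA range, grouped into connected components through shared
metabolites. Detection only: resolving a cycle by directionality curation
is a modeling judgement left to the user.

## Alternate-optima enumeration

Variables are the fluxes `v` plus one binary pair per flux of interest with
`y_i + w_i = 1`; `w_i = 0` collapses `v_i`'s bounds to zero through exact
big-M linking at the global box bound (M = 1000, so the linking is exact,
not approximate). After each MILP solve the nonzero-support set
`NZ_j = {i : |v_i| > 1e-6}` is recorded and the cut
`sum_{i in NZ_j} y_i >= 1` added; the objective is held at
`v_bio >= Z (1 - 1e-6)`. Iteration stops at infeasibility (the useful
outcome: a certificate that every optimal support contains some found
pattern) or at `max_iterations` (default 50, comfortably above the 2–17
solutions typical of genome-scale redox-sink analyses). If the first
solution uses none of the fluxes of interest the all-zero pattern is
returned alone — there is nothing to cut. Results are reported as a set of
support patterns, the stable order-independent summary; solver tie-breaking
among optima is accepted as-is. `rank_by_measurement` orders solutions by
Euclidean distance to measured fluxes — a post-hoc convention for picking
"the" reported solution, not part of the algorithm.

With uptake bounds expressed as capacities (`lb = -rate`), an optimum may
exist that avoids all sinks; chemostat-style simulations that fix uptakes
at measured values (`lb = ub = -rate`) force the surplus reducing power
into the sink set and expose the full pattern family.

## Essentiality and classification

Reaction knockouts set bounds to (0, 0) and re-solve; "essential" means the
knockout optimum falls below the growth threshold (no fractional-growth
tiers). Gene knockouts evaluate every GPR under the deletion — AND for
complexes, OR for isozymes, empty rules always active — and disable the
reactions whose rule goes false. Deletions are judged against the wild-type
optimum computed once. The four-way classification takes essential
reactions from the deletion screen; the remainder are split by FVA at the
fixed optimum (active vs inactive at the 1e-6 threshold), and the inactive
ones re-tested in the fully open system to separate condition-specific
inactivity from genuinely blocked reactions.

## Biomass objective and COD dry weight

Coefficients are `1000 * f * m / MW` mmol precursor per gDW. Storage
polymers (PHB, glycogen) are excluded — they vary strongly with carbon
source and condition and are modeled as demand reactions — and the
remaining fractions plus the unassigned residue are renormalized so the
drained bundle represents 1 g. The measured compositions bundled here sum
to ~95%; the residual is treated as inorganic ash (an explicit inert
pseudo-precursor with a bookkeeping MW of 100 g/mol) and reported, never
silently absorbed. A `renormalize=False` escape hatch applies raw fractions
unscaled, in which case coefficients are exactly linear in the fractions.
Condensation polymers release one water per monomer; growth-associated
maintenance (GAM) appears as ATP hydrolysis with a default of 40 mmol
ATP/gDW — the estimation procedure for GAM is out of scope, so the value is
a prominent, user-overridable knob.

The bundled monomer profile is deliberately coarse: 20 amino acids at
generic bacterial mass fractions, nucleotides derived from a GC content of
0.69, and single representative species for lipids, pigments, LPS and cell
wall. It yields a plausible theta (~1.38 gCOD/g photo) but not the ~1.6 of
a fully resolved composition; organism-specific profiles can be supplied to
`formulate_bof` and verbatim coefficient tables can bypass formulation
entirely.

Dry weight: `dW = (COD_biomass - 1.67 m_PHB - 1.18 m_glycogen) / theta`,
theta = 1.62 (photosynthetic) or 1.56 (aerobic) mgCOD/mg or computed from a
BOF's own electron content at 8 gCOD per electron-mole; inconsistent
measurements (storage COD exceeding total COD) raise.

## Electron accounting and H2 analysis

Degrees of reduction use the half-reaction reference states CO2 / H2O /
NH3 / sulfate / phosphate: `gamma = 4C + H - 2O - 3N + 6S + 5P - charge`.
The ledger counts every boundary flux times its metabolite's gamma plus the
biomass drain's reactant electrons; species without formulas (photons,
proton-motive force, internal carriers) contribute zero and are listed as
skipped. The production envelope fixes biomass on an even grid over
[0, optimum] (101 points by default) and maximizes/minimizes the target at
each point; the grid point at the optimum reproduces the FVA maximum. The
electron fit regresses H2 electron outflow on substrate electron inflow by
least squares and rejects degenerate designs. Competing-sink analysis is a
greedy loop — knock out the candidate sink whose elimination most increases
the max target flux at the (re-computed) growth optimum, skip candidates
whose loss kills growth, stop at no gain — with candidates defaulting to
boundary reactions over electron-carrying products.

## Synthetic fixtures: what a green test establishes

The mini-phototroph is electron-closed with small-integer stoichiometry, so
its optima are hand-derivable: growth 0.75 1/h on succinate 1.57 +
glutamate 0.75 (nitrogen-limited), max H2 2.74 at the optimum and 17.74 at
rest, a conditionally essential NADH dehydrogenase (essential on
succinate + ammonia, where its reverse flux is the only anaerobic quinol
outlet; dispensable on glutamate), isozyme and complex GPRs, a blocked
dead-end, and a DMSO reductase that is inactive photoheterotrophically but
unblocked in the open system. `random_network` plants a linear pathway of
known yield and adds only decoys that terminate in dead ends, so the
planted optimum is provable by construction. `chemostat_measurements`
perturbs consistent steady-state measurements with relative Gaussian noise
from an explicit seed.

These fixtures validate the *algorithms* — LP/MILP correctness against an
independent solver stack, exact electron conservation, planted-feature
detection, closure and recovery arithmetic. They do not emulate
genome-scale properties: no thermodynamically uncertain directionalities,
no thousands-reaction degeneracy, no regulatory silencing of feasible
states, and interior envelope peaks at suboptimal growth (a genome-scale
phenomenon) do not occur in the small fixture, whose envelope is linear in
the biomass flux. Reproducing published genome-scale numbers additionally
requires the deposited SBML model and its exact medium composition, which
are external inputs to this package.

## Known limitations

* No loopless-FBA or thermodynamic flux constraints; cycles are detected
  and reported, not removed.
* No double/combinatorial deletions and no regulatory constraints.
* Light is a photon-exchange flux; no irradiance-to-flux conversion or
  photoinhibition.
* Sweeping a biomass-composition variant is done by constructing the
  variant model (see the BOF-variant test), not through `parameter_sweep`,
  which handles bound-valued parameters only.
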