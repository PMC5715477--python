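# Methods

## The flux-minimization model

All analyses rest on one linear program.  A compartmentalized
stoichiometric model defines `S·v = 0` over internal metabolites with
bounds `LB ≤ v ≤ UB`; the biomass transporters are pinned to fixed fluxes
(experimentally defined proportions), a generic cytosolic ATPase carries a
maintenance demand of 0.1 flux units, and nutrient/photon uptakes are free
unless a scenario fixes them.  The objective is the weighted L1 norm
`Σ wᵢ|vᵢ|`, linearized exactly by the split `v = v⁺ − v⁻` with
`v⁺, v⁻ ≥ 0`; no reformulation that only penalizes forward flux is used,
so reversible reactions are costed correctly.  The flux unit is
dimensionless throughout: only ratios of fluxes are meaningful, and all
scenario parameters are quoted in the same unit.

LPs are solved with scipy's HiGHS backend at primal/dual feasibility
tolerance 1e-9.  Reported fluxes below 1e-9 are clamped to zero, three
orders of magnitude below the 1e-6 tolerance used for mode signatures and
consistency verdicts, so a sign can never flicker across that boundary.
Unbounded directions are excluded by encoding "unconstrained" bounds as
±1e6 flux units.

**Alternative optima.**  L1-minimal flux states are generally degenerate.
The engine returns one vertex deterministically (fixed variable order,
fixed solver settings), and every scientific claim about an individual
flux in the test suite is either certified unique by FVA or stated as a
property that holds across optima.  The FVA side-constraint
`Σ w|v| ≤ Z* (1 + tol) + 1e-7` uses the same split variables; the default
relative tolerance is 0 (strict optimality) and the absolute 1e-7 slack
only guards against an empty interior from round-off.

## Scenario construction

**Vc/Vo lumping.**  Carboxylation and oxygenation are removed and replaced
by a single irreversible reaction whose stoichiometry is the coefficient-
wise sum `a·carb + b·oxy` for a ratio `a:b`, computed in exact rational
arithmetic (stoichiometries are `fractions.Fraction` end to end and only
become floats inside the LP).  The sum is deliberately not normalized by
`a+b`: one unit of lumped flux performs exactly `a` carboxylations and `b`
oxygenations, so Vc and Vo can be read off the lumped flux by
multiplication.  Scans cover 1:1 to 5:1; 3:1 stands for normal air, lower
ratios for drought-like high photorespiration.

**Light scan.**  The photon influx is fixed (equality) at each grid value,
default 0.33 to 10.00 in steps of 0.01, with the additional linear
constraint `v_cyclic − v_noncyclic ≤ 0`.  Grid points are solved
independently, so results are invariant to grid order; points below the
light-limitation threshold are recorded as infeasible rather than fatal.
The threshold itself is located by bisection on LP feasibility to 1e-4.

**Derived metrics.**  Quantum demand is photon influx divided by net CO₂
uptake (undefined when uptake is not positive).  ATP and NADPH totals are
yield-weighted photophosphorylation fluxes; the yields are configuration
with defaults of 3 ATP + 2 NADPH per unit of non-cyclic and 2 ATP per unit
of cyclic photophosphorylation, matching the lumped light-reaction
stoichiometry of the synthetic model.

**Enzymatic-cost ensembles.**  Each iteration draws an independent uniform
weight on [0, 1000] for every enzymatic reaction; transporters (both
categories), photophosphorylation, exchanges and the maintenance reaction
keep a fixed baseline weight of 1.  A baseline of 0 would make transport
free and admit unbounded futile shuttling, hence 1.  Weights are
continuous, so objective ties between routes are measure-zero and the
optimizer's route choice is almost surely unique per draw.  Per-iteration
seeds derive from the master seed by a counter-based scheme
(`SeedSequence(master, spawn_key=(i,))`), making runs order-independent
and exactly reproducible.  Solver failures count as infeasible iterations;
mode counts plus infeasible always sum to n.  A mode is the componentwise
sign pattern (+/0/−, dead zone 1e-6) of a tracked reaction set; presets
cover the chloroplastic/mitochondrial transporters, the Glu–Gln
transporter with the two glutamine synthetase isoforms, and the
peroxisomal H₂O₂-disposal alternatives.

**Correlation.**  Absolute Pearson coefficients of each reaction's flux
series against the scan parameter, computed over feasible points only
(infeasible points dropped pairwise).  Series with variance below 1e-12
carry no information and are set aside.  |r| ∈ [0.9, 1] is "strong" (both
edges closed); the moderate/weak cut at 0.5 is a package default with no
deeper justification and is configurable.

## Consistency checks

The closed-system checks operationalize mass/energy/redox conservation:
with all exchanges and biomass transporters closed and the maintenance
demand forced to zero (it would otherwise mask leaks), (i) a temporary
drain per internal metabolite is maximized — any optimum above 1e-6 is a
leak; (ii) a currency discharge (ATP + H₂O → ADP + Pi, or the analogous
NAD(P)H probe) is maximized — any positive optimum is an energy-generating
cycle.  The elemental audit checks `Σ coeff·composition = 0` per element
for every reaction whose species are all annotated; exchanges and biomass
drains are system boundaries and exempt.  Thermodynamic (ΔG-based)
consistency is out of scope.

## The synthetic core leaf network

The generator emits a curated 86-reaction, four-compartment network: the
condensed Calvin cycle (RuBisCO carboxylase and oxygenase as separate
reactions, PGK/GAPDH, a lumped 5 GAP → 3 Ru5P regeneration step, Ru5P
kinase), the complete photorespiratory loop across chloroplast, peroxisome
and mitochondrion, GS2/GOGAT plus optional cytosolic GS1 with the Glu–Gln
and Mal–2OG/Mal–Glu antiports, malate valves in all three organelles,
triose-phosphate transporters, a mitochondrial chain with proton-pumping
(COX) and non-phosphorylating (AOX) branches at P/O 2.5, peroxisomal
catalase with a glutathione–ascorbate alternative, cytosolic sucrose and
glycerol-3-phosphate synthesis, nitrate reduction, and exchanges for
photons, CO₂, O₂, NH₃, NO₃, Pi, sulfate and water.

Every metabolite carries a simplified elemental composition (C, H, O, N,
P, S; real formulas for small metabolites, cofactor couples differing by
exactly H₂ or HPO₃; photons and proton-motive force are massless), so the
network is elementally balanced reaction by reaction and passes the
closed-system leak and energy-cycle screens by construction.

Deliberate curation choices, made once and frozen:

* **Light stoichiometry**: 8 photons per unit of non-cyclic
  photophosphorylation (3 ATP + 2 NADPH) and 4 per unit of cyclic (2 ATP),
  giving a realistic quantum demand near 9 photons per CO₂ at the
  light-limited optimum.
* **Chloroplastic NADP-MDH is irreversible** toward malate.  In vivo the
  enzyme is thioredoxin-activated in the light and acts as the export
  valve for chloroplast reducing power; making it directional prevents the
  LP from running the valve backwards as a spurious NADPH source.
* **Biomass demands** (GAP 0.02, sucrose 0.004, glycerol-3-phosphate 0.01
  flux units, maintenance 0.1): chosen so that (a) the light-limitation
  threshold (1.25) falls inside the standard 0.33–10.00 photon grid, and
  (b) the cytosolic ATP demand sits between the mitochondrial ATP
  available at Vc/Vo 1:1 (when glycine decarboxylase NADH is plentiful)
  and at 3:1 — the window in which the GAPDH/PGK switch is observable.
* **No nitrogen in biomass.**  The nitrogen cycle is therefore purely
  photorespiratory, which makes the refixation identity exact: at steady
  state the ammonia released by glycine decarboxylase must equal the
  chloroplast NH₃ import and the GS2 flux.

The manifest declares six expected behaviors (consistency, malate-valve
decline with rising Vc/Vo, the GAPDH/PGK switch, complete GS2 refixation,
photorespiratory dissipation rising with fixed light, cyclic ≤ non-cyclic)
and `verify_behaviors` re-derives each one by running the actual scenario
operations, so the generator's claims are checked, not asserted.

**What the generator does and does not emulate.**  It reproduces the
qualitative flux logic of a C3 leaf source tissue — pathway alternatives,
organelle shuttles, energy and redox budgets — at a size where every LP is
exact and fast.  It does not attempt the scale (≈10³ reactions), the gene
associations, the full biomass equation or the secondary metabolism of a
genome-scale reconstruction; passing tests on it demonstrates the
correctness of the machinery and the reachability of the canonical
responses, not quantitative agreement with any particular genome-scale
model's flux values.

## Problem sizes and determinism

The default test-and-verification workload keeps scans coarse where
fine resolution adds nothing: behavior checks use a 0.5-step light grid
over 2–10, the acceptance script a 0.1-step grid over the full range, and
ensembles run at n = 3000 (fixtures) and n = 400 (core model).  Symmetric
k-arm fixtures give analytic mode probabilities 1/k; empirical frequencies
are required to land within three binomial standard errors, the standard
for a seeded stochastic check.  All randomness flows from explicit seeds;
identical inputs give byte-identical tables.

## Known limitations

* One optimum is reported per solve; biological claims based on a single
  vertex of a degenerate optimum need FVA certification (the package does
  this in its own tests).
* The energy-cycle check probes named currency pairs rather than proving
  the absence of all thermodynamically infeasible loops.
* SBML round trips convert rationals through floats; simple ratios are
  recovered exactly via `limit_denominator(10⁹)`, pathological
  denominators would not be.
* The glutathione–ascorbate alternative is reachable (adverse catalase
  weights select it) but rare under the default uniform weighting; runs at
  ensemble sizes of a few hundred may never sample it.
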