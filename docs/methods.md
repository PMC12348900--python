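# Methods

This note documents the models implemented in `actd-cbm`, the defaults
and their rationale, the numerical choices, what the synthetic toy world
does and does not emulate, and the design decisions taken where several
readings were defensible.

## Network representation

Every reaction is represented by two irreversible flux variables
`vf, vb ≥ 0` with net flux `v = vf − vb`. This split makes the weighted
total-flux objective `Σ wᵢ(vf,ᵢ + vb,ᵢ)` linear (it is `Σ wᵢ|vᵢ|` at any
optimum, since carrying both directions simultaneously is never
parsimonious). SBML net bounds `[lb, ub]` map to
`lb_f = max(lb,0), ub_f = max(ub,0), lb_b = max(−ub,0), ub_b = max(−lb,0)`;
writing inverts the map via `[lb_f − ub_b, ub_f − lb_b]`. A reaction with
both a positive forward lower bound and an open backward direction has no
net-bound equivalent; the writer warns and stores the net range.

Exchange reactions follow the export convention `species_e →`: the
forward direction secretes, the backward direction takes up. A *medium*
is a map from exchange ids to maximal uptake rates (mmol·gDW⁻¹·h⁻¹);
applying it caps listed uptakes, closes unlisted ones, and opens
secretion up to a conventional cap of 1000. The uptake sign convention is
declared, not inferred from any external source; the SBML files written
by this package are self-consistent under it.

GPR rules are AND/OR trees over gene identifiers (AND = enzyme complex,
OR = isozymes). Knockouts deactivate a reaction when the rule evaluates
false; the knockout of a multi-gene complex target removes all its
subunits at once.

## Lumped protein turnover

Synthesis of one gram of protein from free amino acids consumes the
residues `n_Aj`, hydrolyzes `k_ATP` ATP per peptide bond
(`k_ATP ∈ [4, 4.3]` for translation including activation; default 4,
minimum 1), and nets `(k_ATP − 1)` waters consumed per bond: each bond
condensation releases one water while each ATP hydrolysis consumes one.
With `M_prot = Σ n_Aj·M_Aj − B·M_H2O` (average residue masses; average,
not monoisotopic, because the stoichiometry is per gram of bulk protein)
the coefficients are `S_x = 1000·(count)/M_prot`, so *one unit of
synthesis flux turns over exactly one gram of protein per gDW per hour*.
The cofactor masses satisfy `M_ATP + M_H2O = M_ADP + M_Pi + M_H+`
exactly, which makes the synthesis reaction close its mass balance
identically; the test suite verifies residuals below 10⁻⁶ g/g on random
sequences up to length 500.

Degradation is modeled as pure hydrolysis (protein + B waters → free
amino acids) with no ATP or ubiquitin stoichiometry — proteasomal
energetics are not quantified here — and the released amino acids re-enter
the compartmental pools (recycling). Degradation products can instead be
routed to a secreted species with its own exchange, which is how
muscle-wasting models export peptide fragments.

## Two-stage pMOFBA

Stage 1 solves the objectives lexicographically in priority rank order:
optimize, freeze at the attained level, move to the next rank. Freezing
uses a relative slack of 10⁻⁶ (plus a 10⁻⁹ absolute floor) so that later
stages are never rendered infeasible by solver rounding; the same slack
is applied to the stage-2 objective constraints, which keeps the ς = 1
solution within 10⁻⁶ relative of the stage-1 optima. Lexicographic
ordering was chosen over weighted sums because the hierarchy of the
objectives (biomass first) is an explicit modeling statement, not a
trade-off to be tuned; a weighted-sum mode is not offered.

Stage 2 minimizes `Σ wᵢ(vf,ᵢ + vb,ᵢ)` under `z ≥ ς·z*` for every
maximized objective. A *literal* dialect (`paper_literal=True`)
constrains only the top-priority objective from below and caps the
remaining maximized objectives from above (`z ≤ ς·z*`); both directions
are defensible readings of "relaxing an attained level", but the cap
direction conflicts with maximization — under a forced maintenance flux
it can even be infeasible for ς below the forced level, which the tests
demonstrate. The default is therefore the downward relaxation, with the
cap dialect kept for comparison.

Weights come from quartile classes of one expression condition: levels
`≥ Q3` are high confidence (w = ¼), `[Q2, Q3)` medium (½), `< Q1`
negative (¾), and everything else — including reactions without usable
gene information — carries w = 1. Quartiles are linear-interpolation
sample quantiles; a fully degenerate profile (Q1 = Q3) classifies every
gene as "none". Through GPR rules the class propagates as min over AND,
max over OR, with "none" children excluded unless all children are
uninformative. Note the weight map is deliberately non-monotone at the
bottom: "clearly off" (negative, ¾) is cheaper than "no information"
(1), so flux is steered away from unknowns more than from silenced
pathways.

All LPs are solved with scipy's HiGHS backend, which is deterministic;
no seeds are involved in the solves.

## pMFVA and biomarker classification

The flow of a metabolite is its total production rate; at steady state
it equals total consumption, an identity the tests verify to 10⁻⁶ on
solver output. The primary variability mode sweeps ς over an 11-point
uniform grid on [0, 1] (the grid density is a configurable default;
envelope containment under refinement to 101 points is tested). The
literal bilevel alternative — max/min of one flow at fixed ς under a
parsimony cap `Σ w(vf+vb) ≤ (1+ε)·UFD optimum`, ε = 10⁻⁴ — is provided
as `flow_fva_mode`.

Disease/healthy comparison uses a two-sided Wilcoxon rank-sum test on
the two ς-series (α = 0.05, raw p-values, no multiple-testing
correction) and classifies significant changes from the envelopes
`D = [d⁻, d⁺]`, `H = [h⁻, h⁺]`:

* CI if `d⁻ ≥ h⁺` (disjoint, above); CD mirrored;
* containment (either envelope inside the other) → II if the disease
  median is higher, ID if lower; median ties fall back to means, exact
  ties to NS;
* remaining overlaps → PI if both endpoints shifted up, PD if down.

The class names (complete / partial / inclusive) drove this interval
algebra; it is a declared convention, chosen for being exhaustive and
antisymmetric under swapping the two conditions (verified by test). A
metabolite is medium-independent iff its class is CI in all media or CD
in all media — a single discordant medium removes the flag.

## Fuzzy target discovery

For each medium the evaluator computes untreated templates (CA for the
disease model, HT for the healthy model) by pMOFBA at ς = 1, then
applies the candidate and re-solves.

* `η_CV`: each disease objective is graded by a decreasing linear
  membership with LB = 0 and UB = its untreated optimum, and the grades
  are aggregated by minimum (Bellman–Zadeh max–min reading: a treatment
  is only as good as its least-suppressed objective). The priority
  hierarchy is expressed through the membership breakpoints, not through
  weights. An infeasible treated disease model scores 1 (the intervention
  is outright lethal to the diseased cell). Objectives whose untreated
  optimum is numerically zero are graded by a narrow (10⁻⁹) band so that
  keeping them at zero scores 1.
* `η_MD`: per monitored flux (default: all reactions), similarity is a
  two-sided membership centered on the HT template flux with half-width
  `max(0.2·|flux|, 10⁻³)`, and dissimilarity is one minus the analogous
  membership centered on the CA template flux; `η_MD` is the 50/50
  average of the two mean grades. Minimum aggregation would be degenerate
  here — any single rerouted flux would zero the grade — hence the mean.
  An infeasible perturbed healthy model scores 0 (maximal side effect).
* `η_D = min` over all `η_CV` and `η_MD` components across disease
  models and media (configurable to mean).

Upregulation is encoded as a minimum-flux constraint: every still-active
reaction depending on the target gene gets a lower bound of
`magnitude × |template flux|` in the template's direction, capped at the
existing upper bound (default magnitude 2). This is the simplest
monotone LP encoding of "more enzyme"; kinetic effects are out of scope.

The nested HDE searches the finite candidate space (single targets and
disjoint pairs over genes/complexes with allowed modes). Individuals are
continuous slot vectors rounded to intervention indices, with an explicit
"empty" index so single-target candidates are reachable; DE/rand/1 with
binomial crossover (population 20, F = 0.5, CR = 0.8 by default) and
greedy selection evolves them, and a migration operator re-seeds all but
the best individual when diversity collapses in either the continuous
genotype (mean std < 10⁻³) or the decoded candidate space (≤ max(2,
pop/4) distinct candidates). All randomness flows through one seeded
generator; runs are reproducible bit-for-bit per seed. Evaluations are
memoized per candidate, so the search never re-solves LPs for revisited
candidates.

## The synthetic toy world

The generator stands in for the real inputs of the workflow (a
genome-scale human reconstruction plus tumor/control expression cohorts)
with a ~30-reaction pair of networks sharing one reaction set:

* glucose and ammonium exchanges, phosphate/proton/water exchanges, a
  biomass drain, a forced ATP maintenance flux (3.0 in disease vs 1.0 in
  healthy mmol·gDW⁻¹·h⁻¹), parallel glycolytic branches with an OR-ruled
  isozyme pair, an AND-ruled respiration complex, amino-acid synthesis
  and an optional lumped cytokine via the protein module;
* *planted lethal gene*: the disease cell imports glucose exclusively
  through transporter gene `gT`, the healthy cell exclusively through
  `gALT`; knocking out `gT` starves the disease model (infeasible forced
  loads → η_CV = 1) and leaves healthy flux untouched;
* *planted biomarkers*: lower-bound-forced synthesis-and-secretion routes
  present only in the disease network (flow ≥ 2 vs 0 → complete increase)
  or only in the healthy network (complete decrease), guaranteeing
  disjoint flow envelopes in every feasible medium;
* disease and healthy differ additionally in biomass composition and ATP
  cost and in the basal flux of the last glycolytic branch (0.5 vs 0.1),
  which keeps the two untreated templates separated across the growth
  machinery, so that any candidate that perturbs the healthy cell beyond
  the lethal knockout strictly loses similarity grade — this is what
  makes the planted optimum unique in the candidate space;
* five media varying the glucose/ammonium caps with ±10% seeded jitter
  (all feasible by construction; an optional starvation medium is
  infeasible on purpose), and expression tables with planted quartile
  membership per condition under log-normal jitter small enough (σ = 0.15
  on the log scale) never to reorder the class bands.

What passing on this world shows: the algebra, LP formulations,
classifiers and search behave exactly as specified on networks whose
ground truth is provable by construction and checkable by exhaustive
enumeration. What it does not show: behavior at genome scale (thousands
of reactions, degenerate alternative optima, numerically hard LPs),
realistic RNA-Seq count distributions (only the quartile structure is
emulated), or the biology of any specific target — the planted optimum is
correct by construction, not a biological claim.

## Problem sizes and runtime choices

Defaults used by the test suite and the acceptance script: toy world
with 29 reactions per network, 5 media, 11-point ς grid, candidate space
of 26, HDE with population 16 for 25 generations, 20 seeded recovery
runs, and vertex-enumeration LP oracles on random chain networks of ≤ 6
reactions (where exhaustive enumeration of basic feasible solutions is
exact and fast). These sizes keep every oracle exhaustive and the full
pipeline reproducible in seconds while exercising all code paths; they
are package defaults, configurable upward.

## Known limitations

* No thermodynamic (loopless) constraints; futile cycles are suppressed
  only by flux parsimony.
* No QP parsimony variant, no flux sampling.
* Upregulation semantics are an LP surrogate; overexpression effects that
  reduce flux elsewhere (resource costs) are not modeled.
* The MD monitored-flux set defaults to all shared reactions; clinically
  informed subsets change the grade's scale.
* Cell-specific model reconstruction from expression data is out of
  scope: networks arrive ready-made (here, from the generator).
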