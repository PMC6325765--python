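# Methods

## Model representation

A metabolic model is a list of metabolites and reactions with signed
stoichiometry, flux bounds in mmol/gDW/h, boolean gene–protein–reaction (GPR)
rules, subsystems, and a single biomass objective.  Naming follows iYO844
conventions (upper-case reactions, lower-case metabolites; uptake is a
negative exchange flux).  GPR rules are AND/OR trees: AND requires all genes
present, OR any; gene knockouts zero every reaction whose rule evaluates
false.  Operon deletions can equivalently be given as explicit reaction
knockouts (both bounds set to zero; both split directions in irreversible
form).

Irreversible conversion splits every two-way reaction R into `R_f`/`R_r`
(reverse with negated stoichiometry); uptake-only exchanges just flip sign.
The net flux v = v_f − v_r and the mapping is carried in model annotations,
so all high-level results are reported in the original (net) reaction
namespace.

## Enzyme constraints

**Per-reaction caps (default).** For each curated entry the (irreversible)
reaction consumes a pseudo-metabolite `prot_<gene>` with coefficient
1/kcat (kcat converted to h⁻¹; entries always store s⁻¹), produced by a
`usage_<gene>` variable bounded above by the enzyme abundance [E] in
mmol/gDW.  Steady state then enforces v ≤ kcat·3600·[E].  A reversible
constrained reaction is capped independently in each direction (curated
entries are written unidirectionally, so this is a conservative fallback).
Abundances are upper 95% confidence limits of absolute proteomics
(molecules/cell converted with 6.3×10⁸ cells/mL/OD and 0.48 gDW/L/OD, and
Avogadro's number fixed at 6.02214076×10²³), a deliberately permissive choice
so the caps do not over-constrain; enzymes below the detection limit get the
dataset-minimum 6.8×10⁻⁸ mmol/gDW and are flagged.  Specific activities
convert to kcat as SA×MW/60 with MW in kDa treated as exactly g/mmol.

Integrating capacity constraints makes carbon uptake an *output* of the
model, so the glucose exchange bound is released when building — to −100
mmol/gDW/h rather than truly unbounded, keeping every LP bounded.

**Total-pool variant.** Usage variables are individually unbounded but drawn
from a shared mass pool: Σᵢ MWᵢ·eᵢ ≤ f·P_total, with defaults P_total = 0.55
g/gDW and f = 0.0191.  The curated table ships without molecular weights
(they enter only this variant), so pool users supply MW per entry.

## Solution methods

LPs (FBA, pFBA stages, FVA subproblems) are solved with HiGHS through scipy
(`primal_feasibility_tolerance` 10⁻⁹; steady state of reported optima is
asserted to 10⁻⁶).  pFBA maximizes growth, pins it (absolute slack 10⁻⁹,
scale-adjusted), and minimizes total flux on the irreversible form — this
also suppresses futile cycles.

MoMA minimizes ‖v − v_ref‖₂² over net fluxes of the ordinary metabolic
reactions, subject to S·v = 0 and the mutant bounds; enzyme-usage
bookkeeping variables never enter the distance (they are bookkeeping, not
phenotype).  The reference is the wild-type pFBA solution of the *same*
model variant.  The QP is solved with OSQP (eps 10⁻⁹, polishing).  Before
solving, usage variables are substituted out: at steady state each one is
pinned to u = v/kcat_h, so its bound becomes a plain flux cap and a shared
mass pool rescales onto the reaction — an equivalence that leaves the
net-flux polytope untouched but removes the ~10⁻⁵-scale columns that
otherwise stall first-order QP solvers.  A ridge of 10⁻⁹ on the quadratic
makes the split-coordinate problem strictly convex; in net space the
objective is strictly convex already, so the solution is unique.  An
infeasible mutant is reported as status `infeasible` and interpreted
downstream as zero growth.

FVA computes per-net-reaction min/max flux subject to growth ≥ fraction × max
growth (default fraction 0.9, the maximum recomputed per model), and
FV = maxflux − minflux.  FV values are optima of LPs, hence invariant to
solver tie-breaking.

## Evaluation

* Prediction error: ‖exp − pred‖₂/‖exp‖₂ over the measured reactions,
  matched by net reaction id (an id-mapping helper with sign factors covers
  studies that name reactions differently).  The all-zero (no-growth)
  prediction scores exactly 1.
* Essentiality: single-gene MoMA knockouts; predicted essential below
  0.05 h⁻¹.
* kcat randomization: kcat values are permuted among the non-frozen entries
  (abundances stay put), the constrained model rebuilt and the wild type
  re-scored; an infeasible permuted model is recorded as error 1 (the
  zero-prediction limit) with an infeasibility counter, keeping the
  distribution defined.  Fully seeded and bit-reproducible.
* Stepwise inclusion scores constraint subsets (exhaustive up to a
  configurable cap of 2^k subsets, or greedy forward selection) and flags
  the minimal subsets matching the full model's scores within 10⁻⁶.
* FV comparison: counts of reduced/increased/unchanged FVs (tolerance
  10⁻⁹ + 10⁻⁶·FV), ratio of median FVs, paired Wilcoxon signed-rank test
  (exact for n ≤ 25, one-sided "base exceeds constrained" by default), and a
  "major reduction" cluster at a default fold-threshold of 10 — the
  threshold is a knob, not a calibrated constant.  Subsystem enrichment of
  that cluster uses the one-sided hypergeometric (Fisher's exact) test; raw
  p-values are primary, with Benjamini–Hochberg reported alongside.

Note that variability reduction is guaranteed monotone only when the two
models share the same absolute growth floor; running each model at 90% of
*its own* maximum (the default protocol) can loosen the floor for the
constrained model and legitimately increase a few overflow-branch ranges.
The test suite asserts strict monotonicity at matched floors.

## Strain design

γ-PGA synthesis is added as 0.77 glu-D + 0.23 glu-L → pga plus a secretion
exchange (the polymer is not in laboratory-strain reconstructions);
precursor secretion exchanges (akg, glu-L, glu-D) can be added instead.  The
deletion scan simulates every candidate set (default: reactions active in
the wild-type reference, excluding exchanges, biomass and the added
pathway) by MoMA and ranks designs by predicted product flux among those
keeping growth ≥ 10% of wild type, ties broken by growth then id.  The full
growth/production Pareto front is retained, because high-production designs
with collapsed growth (e.g. the 2-oxoglutarate dehydrogenase knockout under
enzyme constraints) are biologically the interesting ones even when the
viability filter excludes them from the ranking.  The "best trade-off" is
thus a pinned, documented operationalization, not a claim of uniqueness.

## Synthetic fixture

The toy network is a carbon-skeleton model (~30 reactions): glucose uptake
capped at 10 mmol/gDW/h, glycolysis, the PPP as an oxidative step plus a
reversible transketolase lump (3 ru5p ↔ 2 f6p + g3p), a TCA cycle with the
OXGDC/SSALy 2-oxoglutarate→succinate bypass, acetate/lactate overflow, an
akg→glu-L→glu-D branch, and a lumped biomass drawing g6p, ru5p, g3p, pyr,
accoa, succoa, oaa and glu-L.  No ATP/NAD/O₂ bookkeeping: energy limitation
is outside the fixture's scope, so passing tests say nothing about
energy-coupled phenomena (P/O ratios, maintenance, true overflow onset);
they do exercise capacity-limited growth, rerouting, essentiality shifts and
knockout design end to end.

Because biomass is the only drain and each precursor has a unique
parsimonious route, the wild-type pFBA solution is a per-growth-unit
coefficient vector scaled by μ, and μ is the minimum of (uptake or capacity)
/ coefficient over the binding constraints — an exact analytic ground truth
recorded with the model and cross-checked against an independent LP stack in
the tests.  Capacities are therefore only accepted on reactions with no
alternative route; a binding cap elsewhere (e.g. PGI, which the PPP can
bypass) is rejected rather than silently breaking the closed form.

Default true capacities: CS 1.5 mmol/gDW/h (binds, μ = 3.0), OXGDC
≈ 4.9×10⁻⁵ (detection-floor abundance — the bypass is effectively off, the
key mechanism behind the design-scan differences), G6PDH 0.5 (latent: binds
only when glycolysis is cut, which turns pfkA and pgi essential exactly and
only under enzyme constraints), GAPD_NAD 12 and PGI 20 (slack).  Flux
measurements are truth × (1 + ε), ε ~ N(0, cv) with cv = 0.10 (replicate
variability is reported as a CV, hence multiplicative noise), clipped so a
flux never flips sign.  Synthetic proteomics emits molecules/cell with the
measured mean within ±ci_width/2 of truth and the 95% upper limit
ci_width/2 above the mean; genes below the detection floor are omitted to
exercise the fallback path.

The fixture's "unconstrained vs constrained" error contrast arises from the
growth overshoot of the uncapped model; it does not emulate the
distribution-shape errors (PPP underestimation, overflow misprediction) seen
with real ¹³C datasets, which require a genome-scale model and literature
fluxes (see `scripts/run_iyo844.py`).

## Problem sizes and determinism

All shipped analyses are desk-scale: the toy model solves in milliseconds,
the randomization test uses 200 of the default 10,000 permutations, and the
replicate study uses 100 seeded noise draws — sizes chosen so the whole
pipeline re-runs comfortably on a laptop while leaving the statistics
clear-cut.  Every stochastic step takes an explicit integer seed
(numpy `default_rng`), and both solvers are deterministic given identical
inputs, so artifacts are exactly regenerable from configuration + seed.

## Known limitations

* Only single-enzyme reactions are constrained; isozyme (OR) and complex
  (AND) usage stoichiometry beyond that is out of scope, as is genome-scale
  automatic kcat matching.
* Proteomic abundances are assumed identical in wild type and mutants
  (except the deleted enzyme), the same assumption the MoMA knockout
  protocol makes.
* No thermodynamic loop-law constraints; pFBA's flux-minimization is the
  only cycle suppression.
* The L2 (quadratic) MoMA is the only adjustment criterion; linear MoMA and
  flux sampling are not implemented.
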