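# Methods

## The modeling problem

Chrysanthemic acid — the acid moiety of natural pyrethrin insecticides —
can be produced in *E. coli* by grafting a heterologous route onto the
isoprenoid network: two DMAPP units are condensed head-to-middle by a
chrysanthemyl diphosphate synthase (CDS), the diphosphate is hydrolyzed to
chrysanthemol by a Nudix hydrolase, and two dehydrogenase steps (an
alcohol dehydrogenase, ADH2, then an aldehyde dehydrogenase, ALDH1)
oxidize it to the acid. The engineering questions this package answers in
silico are the ones that matter for such a strain:

1. which competing consumer of the shared DMAPP precursor drains the most
   flux (the *branch point*),
2. how much product is gained by graded silencing of that branch
   (*debranching*), and
3. which downstream conversion step is the bottleneck, and what co-
   amplifying both steps buys (*copy-number optimization*).

All three are posed on a constraint-based (stoichiometric) model: flux
vectors v satisfy steady state S·v = 0 and bounds lb ≤ v ≤ ub, and
phenotypes are linear-programming optima (FBA). COBRApy/GLPK supplies the
LP machinery; everything specific to the workflow is implemented here.

## Constraints beyond plain bounds

**Expression-scaled capacities.** The capacity of an enzymatic reaction is
capped at its theoretical maximum rate, `Vmax = kcat · Etotal`, with the
active enzyme amount taken proportional to transcript abundance,
`Etotal = θ · TPM`. kcat is in 1/s and fluxes in mmol/gDW/hr, so the
conversion factor 3600 is applied exactly once inside `vmax_bound`; θ
carries units mmol·gDW⁻¹ per TPM unit so Vmax lands on the flux scale. θ
defaults to 1e-5 — with desk-scale TPM values (tens to hundreds) this
places capacities in the 10–10³ mmol/gDW/hr range typical of central
metabolism — and `calibrate_theta` fits a single global θ against one
reference reaction when a measured flux is available. Capacity bounds are
*intersected* with model bounds: a cap can tighten a reaction but never
re-open a closed direction.

**Flux-ratio pins.** A transcriptomics-derived split between two routes is
enforced as the exact linear constraint `b·v_A − a·v_B = 0` for a pinned
ratio a:b. The reference-strain preset pins the mevalonate (MVA) route's
terminal decarboxylase to the methylerythritol-phosphate (MEP) route's
kinase at 6461:1.

**Δ-scaled group caps.** Branch consumption of a precursor is limited to a
fraction Δ ∈ (0,1] of its production-route flux: Σ F_out ≤ Δ · Σ F_in.
Consumption and production are measured as the precursor-directed positive
part of each member's flux, implemented on the solver's forward/reverse
split variables, so a reversible member only counts when actually flowing
toward (or from) the pool. One algebraic point dictates the default set
choice: if F_out and F_in were the *complete* consumer and producer sets
of one metabolite, steady state makes both raw sums (nearly) equal and any
Δ < 1 empties the pool — the constraint would be unsatisfiable at any
operating point with nonzero precursor flux. The preset therefore takes
F_in as the *supply-route* reactions (both precursor pathways' lumped
steps, i.e. the pool's initial production rate) and F_out as the terminal
consumers of the pool excluding the IPP isomerase, which only shuttles
within the C5 pool. Both sets are configurable on `group_cap` /
`cs5_preset`.

**The CS5 preset** bundles the measured reference-strain condition:
glucose uptake capped at 20 mmol/gDW/hr, biomass flux fixed at 1.706,
chrysanthemol secretion floored at 0.0023 mmol/gDW/hr, the 6461:1 ratio
pin and the Δ = 0.4 DMAPP cap. The growth value is applied verbatim on the
biomass pseudo-reaction in the same units as every other flux; whether the
source measurement was a rate in 1/hr is not reconstructible, and the
number is treated as the operating point it encodes. Every preset id can
be re-pointed through an alias map.

## Deterministic baseline flux

Raw FBA optima are degenerate, but a knockdown sweep needs a *unique*
baseline to divide bounds from. `baseline_flux` runs three LP stages:
(1) fix the objective at its FBA maximum; (2) minimize total absolute flux
(parsimonious FBA); (3) on the resulting minimum-total-flux face, compute
each reaction's flux range, and return the L1 projection of the
per-reaction midpoints back onto the face. Stage 3 is a pure-LP centering
tie-break: two symmetric parallel paths carrying a demand of 10 come out
5/5 rather than at an arbitrary vertex, and repeated runs agree to 1e-9.
Feasibility tolerance is 1e-9; reported-value comparisons use 1e-6.

## Multi-objective solves

"Maximize biomass and product simultaneously" is ambiguous, so both
readings are implemented. *Lexicographic* (the default for simulations):
optimize terms in priority order, clamping each at slack × its optimum
(default 0.999) before the next — biomass first, product second
reproduces "stay viable, then secrete". *Weighted*: maximize
Σ wᵢ·(vᵢ/optᵢ) with each term normalized by its standalone optimum; a
zero standalone optimum is a hard error rather than a silent division.

## Branch screening

Consumers of the focal metabolite are read off the stoichiometric matrix
(any reaction able to drain it in an open direction). Capacity ranking
uses expression-scaled Vmax; enzymes catalyzing several reactions (the
ispA-like pair DMATT + GRTT) are aggregated by summing their reactions'
Vmax, with per-reaction values retained. Ties break lexicographically on
reaction id. Rate shares follow the Michaelis–Menten competition
proportion `PRate_j = (kcat_j/(Km_j+[s])) / Σ_i kcat_i/(Km_i+[s])`,
evaluated on a log grid of substrate concentrations (default 1e-3–1e2 mM,
6 points, recorded in output metadata); the shares converge to kcat/Km
proportions as [s] → 0 and kcat proportions as [s] → ∞.

## Knockdown simulation

The targets' bounds are divided by inhibition factors k ∈ {2, 4, …, 256}
starting from their *baseline* fluxes — fold-reduction, not subtraction,
because silencing removes enzyme proportionally; reversible targets are
scaled toward zero in both directions. Each level is re-solved with the
lexicographic biomass-then-product objective, and the factor-1 row *is*
the baseline, so its fold-change is exactly 1. If the constraint set fixes
the biomass flux (the preset does), the fixation is relaxed to an upper
bound during the sweep: a perturbed strain may grow more slowly than the
measured value, and "maximize biomass" must remain meaningful. The
product quantity reported is the secretion flux; the production flux-sum
of the product metabolite is recorded alongside as the alternative
"total flux" reading. Infeasible levels are flagged and the sweep
continues; a zero-flux baseline through the targets is reported as a
degenerate knockdown, and a zero product baseline makes the improvement
ratio a NaN sentinel rather than a division.

## Overexpression sweep

Base capacities for the two dehydrogenase steps come from kinetics ×
expression, which fixes their initial max-rate ratio
`RVmax = (kcat₁·EXP₁)/(kcat₂·EXP₂)` (θ and the unit conversion cancel).
The sweep then releases the ratio and scales each step's upper bound
n-fold over {1, 2, 4, 8, 16, 32} — powers of two, matching the knockdown
convention — solving for maximum product flux per cell. The full n×n grid
is computed; the three reported curves are the f1-only row, the f2-only
column and the diagonal. Because each cell only relaxes upper bounds, the
surface is monotone non-decreasing along both axes by LP theory, and the
package asserts it cell-by-cell.

## Comparative analytics

*FVA Jaccard*: per-reaction interval overlap |A∩B|/|A∪B| under length
measure, sorted ascending (most-changed first). Degenerate intervals
follow measure-theoretic convention: two identical points give 1, a point
against a positive-length interval gives 0. The fraction-of-optimum at
which intervals were computed is recorded (default 1.0).

*Sampling volcano*: per-reaction log2FC of absolute sample means with an
ε = 1e-9 pseudo-flux, p from a two-sided Mann–Whitney rank test (sampling
distributions are non-normal; the choice is recorded in the result
metadata). Significance is exactly `p < 1e-8 AND |log2FC| > 1` — the
thresholds drawn on the reference figures. Sign-flipping reactions are
flagged and excluded from fold-change ranking; zero-variance columns get
p = 1 by convention. p-values scale with the sample count and are
descriptive; n is recorded, and no multiplicity correction is applied.

*Flux-sum*: production turnover Φ = Σⱼ max(S·v, 0), per flux vector or per
sample; at steady state it equals the consumption flux-sum, which the
tests verify pointwise on sampled ensembles.

## Sampling

Coordinate hit-and-run (ACHR) over the flux polytope with FVA-extreme
warmup points, thinning 100, default n = 1000 (the comparison stages use
500 or fewer). The sampler is seeded and bitwise reproducible; it refuses
unbounded regions (any infinite bound) with an instruction to tighten
bounds rather than returning an improper distribution.

## The synthetic test system

The toy network (26 reactions, 19 metabolites) emulates the engineered
chassis end to end: glucose uptake and a lumped central-carbon core; the
native MEP route and heterologous MVA route, two lumped steps each, both
terminating in DMAPP; an IPP isomerase; the competing consumers — the
ispA-like pair (DMAPP+IPP→GPP, GPP+IPP→FPP), a phosphatase shunt to DMAP,
and CDS → chrysanthemol → chrysanthemal → chrysanthemic acid — with
exchange reactions for every secreted species (geraniol and farnesol off
GPP/FPP included). Elemental formulas are `(CH2O)_n` carbon-unit
bookkeeping, so every internal reaction passes the balance check exactly
without carrying cofactors, and the network stays small enough for
exhaustive vertex-enumeration oracles. The biomass pseudo-reaction drains
acetyl-CoA (quota 2) and FPP (quota 0.1): full knockout of the ispA pair
is therefore lethal while graded knockdown is viable — the essentiality
structure the debranching strategy exploits.

Planted ground truth: the ispA analogue's kcat·TPM capacity is 5× its
best competitor (the dominance factor is a generator parameter, ≥1); the
dehydrogenase capacities implied by kinetics × expression at the default θ
are 2.0 (alcohol step) and 0.5 (aldehyde step) mmol/gDW/hr, making the
aldehyde step the planted bottleneck and RVmax = 4. Kinetics and
expression tables apply seeded multiplicative log-normal noise (default
sd 0.2) around the truth; silencing conditions are positive multipliers
(e.g. 0.1223 on the ispA analogue for an 87.77% knockdown).

What the toy does *not* emulate: cofactor and energy balance, gene-rule
logic in flux bounds (capacities come from expression-scaled Vmax, so gene
rules are carried but never evaluated), enzyme crowding, and any mapping
from flux to culture titers in mg/L. Tests passing on the toy show the
algorithms are correct and calibrated on a system with known answers, not
that any particular real strain will behave quantitatively alike; on a
genome-scale model the same code paths apply unchanged, with identifier
aliases pointing the preset at the real reaction ids.

## Problem sizes and defaults used in the bundled analyses

Desk-scale sizes keep every bundled analysis at seconds-to-minutes on one
CPU: 50 randomized instances (≤8 reactions) for the vertex-enumeration
cross-check, 200 noise seeds for the branch-recovery experiment, 500
samples per ensemble (thinning 100) for the volcano calibration, the
9-point knockdown ladder and the 6×6 overexpression grid. The
`scripts/acceptance.py` entry point re-derives all headline numbers from
scratch at these sizes.

## Known limitations

- The group cap's positive-part semantics uses the LP forward/reverse
  split; a solution inflating both split variables at once (a futile
  cycle through one reaction) would loosen the cap. The parsimonious
  stages suppress such points, and none arise in the bundled system.
- Lexicographic slack (0.999) means "biomass first" retains 99.9% of the
  achievable optimum, not 100%; slack 1.0 is available where exactness
  matters more than numerical robustness.
- Baseline uniqueness is guaranteed by construction only up to the L1
  projection's own degeneracy; with GLPK the result is reproducible
  run-to-run regardless.
- The volcano's rank-test p-values depend on sampler autocorrelation;
  thinning 100 makes the two-seed null clean on the toy, but genome-scale
  polytopes may need heavier thinning.
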