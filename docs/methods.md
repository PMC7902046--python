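# Methods

## Scope and intent

`mockomics` produces synthetic — but mechanistically self-consistent —
multiomics and strain-production data, and demonstrates a complete
design-build-test-learn loop on it. The package does not claim biological
realism at the level of enzyme kinetics or regulation: the omics rules are
deliberately simple linear transforms of fluxes, chosen so that the data are
far more structured than random noise while remaining cheap to generate at
any scale. What the package *does* treat rigorously is the optimization
layer (FBA, MOMA), the batch mass balance, determinism and seeding, and the
interchange formats.

## Flux solving

FBA maximizes the biomass flux subject to `S·V = 0` and per-reaction bounds,
solved with scipy's HiGHS simplex. FBA optima are generically non-unique, so
the objective is then fixed at its optimum and the squared Euclidean norm of
the flux vector is minimized. This secondary QP has a strictly convex
objective and therefore a unique solution, making every downstream quantity
(omics tables, trajectories, design productions) a deterministic function of
the model and conditions. The tie-break also suppresses futile cycles, which
carry norm but no benefit. Exact flux-level agreement with other FBA
implementations is not expected — only objective-level agreement — since
alternate-optimum resolution differs between solvers.

MOMA (minimization of metabolic adjustment) solves
`min ‖V − V_ref‖₂²` under the perturbed bounds, modelling the physiology of
an engineered strain as the smallest flux rearrangement consistent with its
constraints.

Both QPs are box-and-equality-constrained least-squares problems solved by a
dense primal active-set iteration: the equality system stays in a
least-squares KKT solve (so redundant mass-balance rows are harmless), bound
constraints enter by a most-violated rule and leave by a
most-negative-multiplier rule, with a smallest-index anti-cycling rule after
many iterations and a trust-region interior-point fallback
(`scipy.optimize.minimize(method="trust-constr")`) for the rare degenerate
instance. Feasibility is pre-checked with a phase-1 LP in MOMA so that
infeasible (lethal) designs are reported as such rather than solved
approximately. Tolerances: feasibility 1e-9, optimality 1e-8 (module
constants), matching common simplex/interior-point defaults.

## Batch simulation

A batch culture is advanced on a fixed grid (default Δt = 1 h, horizon 24 h,
inoculum 0.01 gDW/L — config-exposed). Per step: solve FBA (or MOMA for an
engineered strain), update `[cell] ← [cell]·exp(μΔt)` and
`[met] ← [met] + v_EX·Δ[cell]/μ`. The exponential factor `Δ[cell]/μ =
[cell](e^{μΔt}−1)/μ` reduces to the linear `Δt·[cell]` as μ → 0, which is
also the explicit fallback when μ ≤ μ_min (default 1e-6/h). The telescoping
form makes the substrate trajectory exact (to solver tolerance) whenever the
flux solution is constant between steps, which is why the fixed-yield test
model tracks the closed-form two-ODE solution to well under 2%.

**Uptake capping.** Exchange lower bounds are raised each step to
`−[met]·μ/Δ[cell]` so no concentration can go negative. Since the cap
depends on μ, cap and solve are iterated to a fixed point (converges in a
few rounds; bound 25). The cap only binds near substrate exhaustion.

**Termination and starvation.** The loop stops at substrate exhaustion
(threshold 1e-3 mM), at μ ≤ μ_min, or at the horizon. A wild-type step that
is infeasible because the residual substrate cannot sustain the model's
constitutive demands (e.g. a product-leak lower bound) is recorded as a
terminal zero-flux, μ = 0 point — starvation, not death. A MOMA-infeasible
step, by contrast, marks the *design* lethal: zero fluxes are recorded from
that point on and the series is flagged; a design lethal from t = 0 reads
out as zero production.

**Engineered-strain propagation.** The engineered strain's cell density and
concentrations are propagated independently from its own MOMA fluxes on the
wild-type time grid, so a design that slows growth also depletes substrate
more slowly. The alternative reading — overlaying MOMA fluxes on the
wild-type trajectory — is available via `overlay_wt=True`. The grid ends
where the wild-type series ends, because design overrides are anchored to
wild-type flux vectors that only exist on that grid; slow growers are thus
right-truncated rather than extrapolated.

## Omics generation

Per time point and reaction j: proteomics `P_j = |V_j|/k + β` with k = 0.1;
transcriptomics `T_j = P_j/q + γ` with q = 0.833; per metabolite i:
`M_i = Σ_j |S_ij V_j|/n_i` (no noise). β and γ are Gaussian with standard
deviation equal to `noise_fraction` (default 0.05) times the signal, drawn
from one shared seeded generator consumed in model reaction order (so row
order cannot change draws), and results are clamped at zero.

The magnitude `|V_j|` (rather than the signed flux) keeps abundances
physical for reversible reactions carrying negative flux while preserving
"no flux → no protein"; `signed_fluxes=True` restores the literal signed
form, which then clamps negative values to zero. The constants k and q are
arbitrary scale factors, not kinetic parameters; metabolomics units are
nominal mM with no volume normalization. These rules are mock by
construction: passing tests demonstrates correct plumbing and calibrated
noise, not that real proteomes follow fluxes linearly.

## Design engine

Categories {0, 1, 2} mean knockout, no modification, and flux doubling. A
category acts as a per-time-point equality override: KO fixes `lb = ub = 0`;
UP fixes the flux to twice the wild-type flux *of the same time point*
(doubling anchored to t = 0 would be inconsistent with applying MOMA at each
point of the series); UP of a zero wild-type flux is a documented no-op.
Initial batches come from `scipy.stats.qmc.LatinHypercube`; coordinates map
to categories by `floor(3x)` clipped to 2, each coordinate's range thus
evenly covered across the three categories. Collided rows are redrawn
individually (preserving the stratification of surviving rows) and the
wild-type design is appended, giving n distinct designs (default 96,
mimicking one 96-well plate — 1.46% of the 3⁸ space).

## Surrogate and recommendation

The recommender reproduces the *interface* of a Bayesian ensemble
recommendation tool — probabilistic per-design predictions and a ranking
over the enumerable space — without its posterior machinery. It is a
bootstrap ensemble of 100 members (default): 30 stochastic gradient-boosted
trees fit on raw categories and 70 ridge regressions fit on one-hot
indicators, each on an independent bootstrap resample. The two families are
complementary: categorical flux designs produce strongly interacting,
cliff-like response surfaces (a knockout that only pays off together with an
upregulation; infeasible combinations reading out as zero) that trees
capture and linear models cannot, while ridge members extrapolate additive
trends into unseen corners of the space that trees, which predict averages
of training leaves, cannot reach. The ensemble mean is the prediction, the
spread the uncertainty; training rows are sorted into canonical order before
resampling, so fitting is invariant to collection order, and all member
seeds derive from one generator.

Recommendation enumerates all `3^d` category vectors (refused above 10⁶),
excludes training designs, and returns the top-k by predicted mean —
pure exploitation, matching single-next-cycle usage; an
expected-improvement acquisition is available via
`SurrogateConfig(acquisition="expected_improvement")`. Ties break by smaller
predicted sd, then lexicographic category order, for determinism.

Cross-validation is k-fold (default 10), each instance predicted exactly
once by an ensemble not trained on it. On a noiseless additive synthetic
surface the cross-validated R² exceeds 0.9; on the toy model's mechanistic
landscape R² is low (~0.1 at 96 training designs) because 96 points cannot
resolve cliff-like interactions among 6,561 designs — yet the *ranking* is
informative enough that in most seeds at least one of ten recommendations
beats the best training design. That gap between pointwise accuracy and
decision quality is characteristic of recommend-then-verify loops.

## Interchange formats

Measurements travel as a generic 5-column CSV: line name, typed measurement
id, time (plain hours), value, unit. Ids are PubChem CIDs for metabolites
(canonical spelling `CID:715`; the spaced variant `CID: 715` is parsed),
UniProt accessions for proteins, GenBank gene ids for transcripts. The unit
vocabulary is closed — FPKM, proteins/cell, mg/L, mM, and the empty string
for optical density, which has no units — and readers reject anything else;
CID-typed ids may only carry metabolite units. Header strings are
config-exposed to match any live repository instance. Floats are serialized
in shortest-exact form so `read(write(x)) == x` holds bit-for-bit. The
experiment-description CSV carries line name, part id (strain-registry
accession) and metadata columns only — never measurement values.

## The toy model

The built-in fixture (15 metabolites, 24 reactions at defaults) stands in
for a genome-scale model with a heterologous product pathway: glucose and
ammonium exchanges; lumped glycolysis to a pyruvate node; two parallel
routes into an acetyl-CoA hub, one losing carbon as secreted formate; an
anaplerotic oxaloacetate/malate loop with parallel routes; secretion valves
for acetate, pyruvate, oxaloacetate and malate; a biomass drain consuming
acetyl-CoA, oxaloacetate, malate and ammonium (scaled so the default yield
gives μ ≈ 0.64/h at 10 mmol/gDW/h uptake — E. coli-like); and a product
branch from acetyl-CoA to extracellular "isoprenol" carrying a constitutive
leak of 0.2 mmol/gDW/h so the wild type has a measurable baseline titer.

Design choices worth recording:

- **Valves emulate redundancy.** With up to eight equality overrides active
  at once, a minimal network would render most multi-modification designs
  infeasible; the secretion valves keep enough degrees of freedom that
  infeasibility is the exception (as in genome-scale networks), while still
  allowing genuinely lethal combinations.
- **Seven of the eight default targets** (PDH, PFL, PPC, PCK, MDH, MAE,
  IPS1) carry wild-type flux so both KO and UP act on them; the acetate
  valve PTA is idle in the wild type, making its categories asymmetric (KO
  matters, UP is a no-op) — a deliberate null-ish feature.
- **The response surface is interaction-dominated.** The best designs work
  by closing overflow valves while overdriving routes into acetyl-CoA,
  forcing surplus carbon through the free product branch; production spans
  0 to ~5.9 mM against a 0.507 mM wild type, roughly 11% of designs improve
  on the wild type, and about two-thirds read zero (severed pathway or
  lethal combination).

The default study conditions are 22 mM glucose and 18 mM ammonium, 0.01
gDW/L inoculum, Δt = 1 h. Reference experiments use 95 Latin-hypercube
designs + WT and k = 10 recommendations.

What the toy model does *not* emulate: realistic E. coli flux values or
yields, gene-protein-reaction logic (designs act on reactions directly),
kinetic uptake laws, thermodynamic constraints, regulation. Passing tests on
it validates the machinery — solvers, propagation, learning loop, formats —
not any organism-specific prediction.

## Problem sizes and numerical choices

The shipped test suite and the acceptance script run entirely on the toy
model: full 96-design cycles take a few seconds each (one LP + one QP per
time point per design, ~10 time points), ten-cycle success-rate estimates
about a minute. Brute-force solver checks use random 6-metabolite ×
10-reaction instances where vertex enumeration (~3×10³ candidate bases) and
the analytic null-space QP solution are exact; the null-space MOMA oracle is
only valid when no box constraint is active at the optimum, so instances
violating that are discarded rather than compared against an invalid
reference. Degenerate inputs: zero initial substrate yields a single μ = 0
time point; an infeasible wild type at t = 0 raises; UP on a zero flux is a
no-op; duplicate designs, duplicate line names, unknown units, and
inconsistent bounds are rejected at validation time.

## Known limitations

- Production readout truncates engineered strains at the wild-type grid end,
  slightly understating titers of slow growers.
- The surrogate's predictive intervals are ensemble spreads, not calibrated
  posteriors; coverage is not guaranteed.
- Genome-scale use (the optional case-study script) is supported but slow:
  the dense active-set QP is sized for hundreds, not thousands, of
  reactions per solve at interactive speed.
- SBML/JSON I/O inherits COBRApy's conventions; models without an objective
  or with non-standard exchange encodings need explicit annotation.
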