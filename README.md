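# mockomics

Synthetic multiomics data generation and surrogate-guided strain design for
metabolic engineering.

Experimental multiomics campaigns are expensive, so tools that store,
visualize, and learn from such data are hard to test at realistic scale.
`mockomics` generates *credible* multiomics data from first principles — a
genome-scale (or toy) stoichiometric model, flux balance analysis, and simple
flux-to-abundance rules — and then closes a complete in-silico
Design-Build-Test-Learn (DBTL) cycle on top of it: categorical strain designs
are "built" with MOMA, their product titers are read out from batch
simulations, a probabilistic surrogate is trained on the results, and new
designs predicted to improve production are recommended and verified against
the same mechanistic ground truth. It is aimed at developers of
machine-learning and data-management tools for synthetic biology who need
large, self-consistent, fully reproducible datasets.

## The model

**Fluxes.** At each batch time point, fluxes solve the FBA linear program

```
max  V_biomass
s.t. Σ_j S_ij V_j = 0          (steady-state mass balance)
     lb_j ≤ V_j ≤ ub_j         (flux bounds, mmol/gDW/h)
```

with `S` the m×n stoichiometric matrix. Because FBA optima are degenerate,
the objective is then fixed at its optimum and `‖V‖₂` is minimized, selecting
a unique, reproducible flux vector. Negative exchange flux means uptake.

**Batch dynamics.** Cell density grows as `[cell]·exp(μΔt)` with μ the
biomass flux; each extracellular metabolite is updated by
`[met] ← [met] + v_EX · Δ[cell]/μ` (the exponential refinement of
`v_EX·Δt·[cell]`), with exchange bounds capped so concentrations stay
non-negative, until the carbon source is exhausted.

**Mock omics.** Per time point: proteomics `P_j = |V_j|/k + β` (k = 0.1),
transcriptomics `T_j = P_j/q + γ` (q = 0.833), metabolomics
`M_i = Σ_j |S_ij V_j| / n_i` over the n_i reactions touching metabolite i;
β, γ are seeded Gaussian noise at 5% of the signal. No flux → no protein,
no transcript, no metabolite.

**Designs.** Each target reaction takes a category from {0: knockout,
1: no modification, 2: flux doubled}, enforced per time point as MOMA bound
overrides against the wild-type flux series (`min ‖V − V_wt‖₂²` under the
modified bounds). Eight ternary targets span 3⁸ = 6,561 designs; an initial
96-well batch (95 Latin-hypercube draws + wild type, 1.46% of the space) is
the training set.

**Recommendation.** A bootstrap ensemble (gradient-boosted trees + one-hot
ridge members) predicts production with uncertainty; the full design space is
enumerated and the top-k unseen designs are recommended.

Measurement tables are read and written in a generic 5-column CSV (line,
typed measurement id — PubChem CID / UniProt / GenBank, time, value, unit)
for exchange with experiment-data repositories, alongside an
experiment-description CSV for line metadata.

## Worked example

One full DBTL cycle on the built-in toy model (13 exchangeable metabolites,
24 reactions, an isoprenol-like product branch on acetyl-CoA):

```python
import numpy as np
from mockomics import (
    make_toy_model, default_conditions, run_wt_batch,
    latin_hypercube_designs, simulate_design_production,
    TrainingSet, fit_surrogate, recommend,
)
from mockomics.fixtures import DEFAULT_TARGET_REACTIONS

model = make_toy_model()
wt = run_wt_batch(model, default_conditions())
print(f"wild type: {len(wt)} time points, "
      f"final isoprenol {wt.final_concentration('ipre_e'):.3f} mM")

batch = latin_hypercube_designs(96, DEFAULT_TARGET_REACTIONS, rng_seed=1)
productions = {
    d.key(): simulate_design_production(model, wt, d, "ipre_e") for d in batch
}
training = TrainingSet(
    X=np.array(list(productions)),
    y=np.array(list(productions.values())),
    reactions=DEFAULT_TARGET_REACTIONS,
)
print(f"best of 96 training designs: {training.y.max():.3f} mM")

surrogate = fit_surrogate(training, rng_seed=1)
recs = recommend(surrogate, k=10, exclude=training)
verified = {
    d.key(): simulate_design_production(model, wt, d, "ipre_e")
    for d, _ in recs
}
best_key = max(verified, key=verified.get)
print(f"best verified recommendation {best_key}: {verified[best_key]:.3f} mM")
```

prints

```
wild type: 9 time points, final isoprenol 0.507 mM
best of 96 training designs: 1.759 mM
best verified recommendation (2, 2, 0, 0, 1, 1, 1, 1): 1.759 mM
```

The wild type makes 0.507 mM of product from 22 mM glucose before exhaustion
at 8 h. The recommended design — doubled PDH and PFL flux with the acetate
and anaplerotic overflow valves knocked out, forcing surplus acetyl-CoA into
the product branch — more than triples that titer (247% over wild type).
Recommendations are ranked by predicted mean with full per-design predictive
distributions (`mean`, `sd`, ensemble samples).

The same workflow is available from the shell:

```
mockomics toy-model --out toy.json
mockomics simulate-wt --model toy.json --out wt/
mockomics designs --n 96 --seed 1 --out designs.csv
mockomics simulate-designs --designs designs.csv --model toy.json --out prods.csv
mockomics recommend --train train.csv --k 10 --seed 1 --out recs
```

## Layout

- `mockomics.model` — model structures, FBA (HiGHS LP + L2 tie-break), MOMA
  (active-set QP)
- `mockomics.io` — SBML-L3 / COBRA-JSON model I/O via COBRApy
- `mockomics.batch` — wild-type and engineered-strain batch simulation
- `mockomics.omics` — flux → proteomics / transcriptomics / metabolomics
- `mockomics.designs` — design space, Latin-hypercube batches, MOMA
  overrides, production readout
- `mockomics.recommend` — bootstrap-ensemble surrogate, cross-validation,
  top-k recommendation
- `mockomics.edd` — generic 5-column measurement CSV + experiment
  description
- `mockomics.fixtures` — toy model and synthetic ground-truth generators
- `mockomics.cli` — `mockomics` command-line entry point

See `docs/methods.md` for modelling assumptions, parameter choices, and
limitations.
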