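"""Self-contained synthetic fixtures: a toy metabolic model and ground truths.

The toy model is a deterministic, hand-built stand-in for a genome-scale
reconstruction augmented with a heterologous product pathway.  It has glucose
and ammonium exchanges, a lumped glycolysis feeding a pyruvate node, two
parallel routes into an acetyl-CoA hub (one of which loses carbon as secreted
formate), an anaplerotic oxaloacetate/malate loop of decoy reactions, an
acetate-overflow drain, a biomass drain on acetyl-CoA plus ammonium, and a
product branch (acetyl-CoA → … → extracellular product) carrying a small
constitutive leak flux so the unmodified strain makes a measurable baseline
amount of product.  At roughly a dozen metabolites and reactions it is large
enough for non-trivial FBA/MOMA geometry yet small enough for brute-force
oracles.

All identifiers (UniProt-style protein accessions, GenBank-style b-numbers,
PubChem-style CIDs) are synthetic labels minted here for omics plumbing; they
do not refer to real database entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .batch import BatchConditions, BatchTimeSeries, run_wt_batch
from .designs import (
    Design,
    NOMOD,
    design_space_size,
    enumerate_design_space,
    simulate_design_production,
)
from .model import MetabolicModel

#: the eight hub-connected reactions used as default design targets
DEFAULT_TARGET_REACTIONS = [
    "PDH",
    "PFL",
    "PTA",
    "PPC",
    "PCK",
    "MDH",
    "MAE",
    "IPS1",
]


@dataclass
class ToyModelSpec:
    """Parameters of the toy model.

    ``branch_yield`` is mol product per mol of hub metabolite entering the
    product branch; ``biomass_yield`` is gDW formed per mmol of substrate
    when all carbon goes to biomass; ``product_leak`` is the constitutive
    lower bound (mmol/gDW/h) on the first product-branch reaction that gives
    the wild type its baseline production.
    """

    n_pathway_steps: int = 2
    branch_yield: float = 1.0
    uptake_max: float = 10.0  # mmol/gDW/h
    biomass_yield: float = 0.065  # gDW/mmol substrate
    target_id: str = "ipre_e"
    product_leak: float = 0.2  # mmol/gDW/h

    def validate(self) -> None:
        if min(
            self.n_pathway_steps,
            self.branch_yield,
            self.uptake_max,
            self.biomass_yield,
        ) <= 0:
            raise ValueError("all toy-model parameters must be positive")
        if self.product_leak < 0:
            raise ValueError("product_leak must be non-negative")


def make_toy_model(spec: ToyModelSpec | None = None) -> MetabolicModel:
    """Build the deterministic toy model described in the module docstring."""
    spec = spec or ToyModelSpec()
    spec.validate()
    big = 1000.0

    # metabolite order fixes S row order; *_e metabolites are extracellular
    mets = [
        "glc_e",
        "nh4_e",
        "g6p_c",
        "pyr_c",
        "accoa_c",
        "for_e",
        "ac_e",
        "oaa_c",
        "mal_c",
        "pyr_e",
        "oaa_e",
        "mal_e",
    ]
    branch_mets = [f"iprei{k}_c" for k in range(1, spec.n_pathway_steps)]
    mets += branch_mets + ["ipre_c", "ipre_e"]

    # biomass drain consumes the acetyl-CoA hub plus the anaplerotic
    # intermediates, scaled so that 2/biomass_yield carbon-precursor units
    # are consumed per unit of biomass flux (2 pyr per glc at the hub)
    pyr_per_biomass = 2.0 / spec.biomass_yield  # ~30 at the default yield
    accoa_coeff = pyr_per_biomass * 14.0 / 30.0
    oaa_coeff = pyr_per_biomass * 9.0 / 30.0
    mal_coeff = pyr_per_biomass * 7.0 / 30.0

    reactions: list[tuple[str, dict[str, float], float, float]] = [
        ("EX_glc", {"glc_e": -1}, -spec.uptake_max, big),
        ("EX_nh4", {"nh4_e": -1}, -big, big),
        ("EX_for", {"for_e": -1}, 0.0, big),
        ("EX_ac", {"ac_e": -1}, 0.0, big),
        ("EX_ipre", {"ipre_e": -1}, 0.0, big),
        ("GLCup", {"glc_e": -1, "g6p_c": 1}, 0.0, big),
        ("GLYC", {"g6p_c": -1, "pyr_c": 2}, 0.0, big),
        # overflow valves: secretion routes for the hub intermediates keep
        # enough degrees of freedom that most doubled-flux designs stay
        # feasible, as in a redundant genome-scale network
        ("PYRt", {"pyr_c": -1, "pyr_e": 1}, 0.0, big),
        ("EX_pyr", {"pyr_e": -1}, 0.0, big),
        ("OAAt", {"oaa_c": -1, "oaa_e": 1}, 0.0, big),
        ("EX_oaa", {"oaa_e": -1}, 0.0, big),
        ("MALt", {"mal_c": -1, "mal_e": 1}, 0.0, big),
        ("EX_mal", {"mal_e": -1}, 0.0, big),
        ("PDH", {"pyr_c": -1, "accoa_c": 1}, 0.0, big),
        ("PFL", {"pyr_c": -1, "accoa_c": 1, "for_e": 1}, 0.0, big),
        ("PTA", {"accoa_c": -1, "ac_e": 1}, 0.0, big),
        # two parallel anaplerotic routes into oaa, and two into mal, give
        # the decoy loop nonzero wild-type flux and graded knockout effects
        ("PPC", {"pyr_c": -1, "oaa_c": 1}, 0.0, big),
        ("PCK", {"pyr_c": -1, "oaa_c": 1}, -big, big),
        ("MDH", {"oaa_c": -1, "mal_c": 1}, -big, big),
        ("MAE", {"pyr_c": -1, "mal_c": 1}, -big, big),
        (
            "BIOMASS",
            {
                "accoa_c": -accoa_coeff,
                "oaa_c": -oaa_coeff,
                "mal_c": -mal_coeff,
                "nh4_e": -8.0,
            },
            0.0,
            big,
        ),
    ]
    # product branch: accoa -> (intermediates) -> ipre_c, yield on first step
    chain = branch_mets + ["ipre_c"]
    first_products = {"accoa_c": -1.0, chain[0]: spec.branch_yield}
    reactions.append(("IPS1", first_products, spec.product_leak, big))
    for k in range(1, spec.n_pathway_steps):
        reactions.append(
            (f"IPS{k + 1}", {chain[k - 1]: -1.0, chain[k]: 1.0}, 0.0, big)
        )
    reactions.append(("IPT", {"ipre_c": -1, "ipre_e": 1}, 0.0, big))

    met_index = {m: i for i, m in enumerate(mets)}
    rxn_ids = [r[0] for r in reactions]
    S = np.zeros((len(mets), len(reactions)))
    lb = np.zeros(len(reactions))
    ub = np.zeros(len(reactions))
    for j, (_, coeffs, lo, hi) in enumerate(reactions):
        for met, coef in coeffs.items():
            S[met_index[met], j] = coef
        lb[j], ub[j] = lo, hi

    # synthetic omics labels for every enzymatic (non-exchange, non-biomass)
    # reaction and every metabolite
    feature_map = {}
    counter = 1
    for rxn in rxn_ids:
        if rxn.startswith("EX_") or rxn == "BIOMASS":
            continue
        feature_map[rxn] = (f"P{90000 + counter:05d}", f"b{counter:04d}")
        counter += 1
    metabolite_measurement_ids = {
        met: f"CID:{880000 + i}" for i, met in enumerate(mets, start=1)
    }

    model = MetabolicModel(
        metabolite_ids=mets,
        reaction_ids=rxn_ids,
        S=S,
        lb=lb,
        ub=ub,
        objective_id="BIOMASS",
        feature_map=feature_map,
        metabolite_measurement_ids=metabolite_measurement_ids,
    )
    model.exchange_map = model.detect_exchanges()
    model.validate()
    return model


def default_conditions() -> BatchConditions:
    """Batch conditions of the reference experiment: 22 mM glucose, 18 mM
    ammonium, 0.01 gDW/L inoculum, 1 h grid, 24 h horizon."""
    return BatchConditions(
        initial_concentrations={"glc_e": 22.0, "nh4_e": 18.0},
        initial_cell_density=0.01,
        dt=1.0,
        max_time=24.0,
        primary_substrate="glc_e",
    )


def make_ground_truth(
    model: MetabolicModel,
    design_space: list[tuple[int, ...]] | None,
    rule: str = "mechanistic",
    reactions: list[str] | None = None,
    rng_seed: int = 0,
    wt_series: BatchTimeSeries | None = None,
    target_id: str = "ipre_e",
    base_production: float = 1.0,
    effect_scale: float = 0.3,
    noise_sd: float = 0.0,
) -> dict[tuple[int, ...], float]:
    """Map category vectors to production values, mechanistically or additively.

    ``rule="mechanistic"`` runs the full MOMA batch readout for every design;
    ``rule="additive"`` draws one effect per (reaction, category≠NoMod) from a
    seeded normal and sums them onto ``base_production`` — a closed-form
    surface for surrogate validation, exactly additive when ``noise_sd`` is 0
    and with seeded Gaussian observation noise otherwise.
    """
    reactions = reactions or DEFAULT_TARGET_REACTIONS
    if design_space is None:
        design_space = list(enumerate_design_space(reactions))
    keys = [tuple(v) for v in design_space]

    if rule == "additive":
        rng = np.random.default_rng(rng_seed)
        effects = {
            (rxn, cat): (0.0 if cat == NOMOD else float(rng.normal(0, effect_scale)))
            for rxn in reactions
            for cat in (0, 1, 2)
        }
        return {
            key: max(
                0.0,
                base_production
                + sum(effects[(rxn, cat)] for rxn, cat in zip(reactions, key))
                + (float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0),
            )
            for key in keys
        }

    if rule != "mechanistic":
        raise ValueError(f"unknown ground-truth rule {rule!r}")
    if len(keys) > 10**5:
        raise ValueError(
            "mechanistic ground truth over >1e5 designs; subsample the space"
        )
    if wt_series is None:
        wt_series = run_wt_batch(model, default_conditions())
    truth: dict[tuple[int, ...], float] = {}
    for key in keys:
        design = Design(dict(zip(reactions, key)))
        truth[key] = simulate_design_production(model, wt_series, design, target_id)
    return truth
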