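#!/usr/bin/env python
"""Optional, network-dependent case study on the iJO1366 E. coli model.

Downloads iJO1366 from the BiGG model repository, splices a synthetic
four-reaction isoprenol branch onto cytosolic acetyl-CoA, and runs the same
design-build-test-learn loop as the toy pipeline with the classic
acetyl-CoA-adjacent targets (ACCOAC, MDH, PTAr, CS, ACACT1r, PPC, PPCK, PFL).

This script is NOT part of the test suite: it needs network access and tens
of minutes of QP solving at genome scale.  The spliced pathway is a synthetic
stand-in (it does not claim to reproduce any published pathway's exact
stoichiometry), so absolute titers are indicative only; the qualitative
expectation is that PPCK knockouts rank among the improving designs.

Usage:
    python scripts/ecoli_casestudy.py --out scratch/ecoli --seed 1
"""

from __future__ import annotations

import argparse
import json
import os
import urllib.request

import numpy as np

import cobra
import cobra.io

from mockomics import (
    BatchConditions,
    Design,
    TrainingSet,
    fit_surrogate,
    latin_hypercube_designs,
    recommend,
    run_wt_batch,
    simulate_design_production,
)
from mockomics.io import from_cobra

BIGG_URL = "http://bigg.ucsd.edu/static/models/iJO1366.json"
TARGETS = ["ACCOAC", "MDH", "PTAr", "CS", "ACACT1r", "PPC", "PPCK", "PFL"]


def fetch_model(cache_path: str) -> cobra.Model:
    if not os.path.exists(cache_path):
        print(f"downloading {BIGG_URL} ...")
        urllib.request.urlretrieve(BIGG_URL, cache_path)
    return cobra.io.load_json_model(cache_path)


def splice_isoprenol_branch(cb: cobra.Model) -> None:
    """Synthetic 4-step branch: accoa_c -> ... -> isoprenol_e (1:1 carbon-naive)."""
    mets = {}
    for mid in ("iprenyl1_c", "iprenyl2_c", "isoprenol_c", "isoprenol_e"):
        mets[mid] = cobra.Metabolite(
            mid, compartment="e" if mid.endswith("_e") else "c"
        )
    cb.add_metabolites(list(mets.values()))
    steps = [
        ("IPS1", {"accoa_c": -1, "iprenyl1_c": 1}, 0.05),
        ("IPS2", {"iprenyl1_c": -1, "iprenyl2_c": 1}, 0.0),
        ("IPS3", {"iprenyl2_c": -1, "isoprenol_c": 1}, 0.0),
        ("IPRt", {"isoprenol_c": -1, "isoprenol_e": 1}, 0.0),
        ("EX_isoprenol_e", {"isoprenol_e": -1}, 0.0),
    ]
    for rid, coeffs, lb in steps:
        r = cobra.Reaction(rid)
        r.lower_bound, r.upper_bound = lb, 1000.0
        cb.add_reactions([r])
        r.add_metabolites({cb.metabolites.get_by_id(m): c for m, c in coeffs.items()})


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", default="scratch/ecoli")
    parser.add_argument("--n-designs", type=int, default=96)
    args = parser.parse_args()
    os.makedirs(args.out, exist_ok=True)

    cb = fetch_model(os.path.join(args.out, "iJO1366.json"))
    splice_isoprenol_branch(cb)
    model = from_cobra(cb)

    conditions = BatchConditions(
        initial_concentrations={"glc__D_e": 22.0, "nh4_e": 18.0},
        primary_substrate="glc__D_e",
    )
    wt = run_wt_batch(model, conditions)
    wt_prod = wt.final_concentration("isoprenol_e")
    print(f"WT isoprenol: {wt_prod:.4f} mM over {len(wt)} time points")

    batch = latin_hypercube_designs(args.n_designs, TARGETS, rng_seed=args.seed)
    productions = {}
    for i, design in enumerate(batch):
        productions[design.key()] = simulate_design_production(
            model, wt, design, "isoprenol_e"
        )
        print(f"  design {i + 1}/{len(batch)}: {productions[design.key()]:.4f} mM")

    training = TrainingSet(
        X=np.array(list(productions)),
        y=np.array(list(productions.values())),
        reactions=TARGETS,
    )
    surrogate = fit_surrogate(training, rng_seed=args.seed)
    recs = recommend(surrogate, k=10, exclude=training)
    report = {
        "wt_isoprenol_mM": wt_prod,
        "best_training_mM": float(training.y.max()),
        "recommendations": [
            {
                "design": dict(zip(TARGETS, key)),
                "predicted_mean_mM": dist.mean,
                "predicted_sd_mM": dist.sd,
                "simulated_mM": simulate_design_production(
                    model, wt, Design(dict(zip(TARGETS, key))), "isoprenol_e"
                ),
            }
            for key, (_, dist) in zip(recs.keys(), recs)
        ],
        "ppck_ko_recommended": any(
            key[TARGETS.index("PPCK")] == 0 for key in recs.keys()
        ),
    }
    out_path = os.path.join(args.out, "casestudy.json")
    with open(out_path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    print(f"wrote {out_path}")


if __name__ == "__main__":
    main()
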