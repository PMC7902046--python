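"""Model file I/O: SBML Level 3 (fbc) and COBRA-style JSON, via COBRApy.

The package's own :class:`~mockomics.model.MetabolicModel` is a plain dense
structure (ids, S matrix, bounds, objective); this module converts between it
and :class:`cobra.Model` so that any genome-scale model readable by COBRApy
can drive the simulators.  Omics labels (protein / transcript / PubChem ids)
travel in the standard annotation slots (``uniprot``, ``genbank``,
``pubchem.compound``) so they round-trip through COBRA-JSON.
"""

from __future__ import annotations

import os

import numpy as np

from .model import MetabolicModel, ModelConfigError, ModelFormatError


def _first(value) -> str:
    if isinstance(value, (list, tuple)):
        return str(value[0])
    return str(value)


def from_cobra(cb_model) -> MetabolicModel:
    """Convert a :class:`cobra.Model` into the package's dense model."""
    from cobra.util.array import create_stoichiometric_matrix
    from cobra.util.solver import linear_reaction_coefficients

    metabolite_ids = [m.id for m in cb_model.metabolites]
    reaction_ids = [r.id for r in cb_model.reactions]
    S = create_stoichiometric_matrix(cb_model, array_type="dense")
    lb = np.array([r.lower_bound for r in cb_model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in cb_model.reactions], dtype=float)

    coeffs = linear_reaction_coefficients(cb_model)
    if not coeffs:
        raise ModelConfigError("model declares no objective reaction")
    objective_id = max(coeffs, key=lambda r: abs(coeffs[r])).id

    feature_map: dict[str, tuple[str, str]] = {}
    for r in cb_model.reactions:
        prot = r.annotation.get("uniprot")
        gene = r.annotation.get("genbank")
        if prot is not None and gene is not None:
            feature_map[r.id] = (_first(prot), _first(gene))

    metabolite_measurement_ids: dict[str, str] = {}
    for m in cb_model.metabolites:
        cid = m.annotation.get("pubchem.compound")
        if cid is not None:
            metabolite_measurement_ids[m.id] = f"CID:{_first(cid)}"

    model = MetabolicModel(
        metabolite_ids=metabolite_ids,
        reaction_ids=reaction_ids,
        S=S,
        lb=lb,
        ub=ub,
        objective_id=objective_id,
        feature_map=feature_map,
        metabolite_measurement_ids=metabolite_measurement_ids,
    )
    # exchanges: trust structure (single nonzero stoichiometric entry)
    model.exchange_map = model.detect_exchanges()
    model.validate()
    return model


def to_cobra(model: MetabolicModel):
    """Convert the dense model into a :class:`cobra.Model` (for writing)."""
    import cobra

    cb = cobra.Model("mockomics_model")
    mets = {}
    for i, mid in enumerate(model.metabolite_ids):
        compartment = "e" if mid.endswith("_e") else "c"
        m = cobra.Metabolite(mid, compartment=compartment)
        cid = model.metabolite_measurement_ids.get(mid)
        if cid is not None:
            m.annotation["pubchem.compound"] = cid.split(":", 1)[1]
        mets[i] = m
    cb.add_metabolites(list(mets.values()))
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        r = cobra.Reaction(rid)
        r.lower_bound = float(model.lb[j])
        r.upper_bound = float(model.ub[j])
        if rid in model.feature_map:
            prot, gene = model.feature_map[rid]
            r.annotation["uniprot"] = prot
            r.annotation["genbank"] = gene
        reactions.append(r)
    cb.add_reactions(reactions)
    for j, rid in enumerate(model.reaction_ids):
        col = model.S[:, j]
        coeffs = {mets[i]: float(col[i]) for i in np.nonzero(col)[0]}
        cb.reactions.get_by_id(rid).add_metabolites(coeffs)
    cb.objective = model.objective_id
    return cb


def load_model(path: str, fmt: str | None = None) -> MetabolicModel:
    """Load an SBML-L3 or COBRA-JSON model file.

    ``fmt`` is ``"sbml"`` or ``"json"``; when omitted it is inferred from the
    file extension (``.xml``/``.sbml`` vs ``.json``).
    """
    import cobra.io

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if fmt is None:
        ext = os.path.splitext(path)[1].lower()
        fmt = {"": "json", ".json": "json", ".xml": "sbml", ".sbml": "sbml"}.get(ext)
        if fmt is None:
            raise ModelFormatError(f"cannot infer model format from {path!r}")
    try:
        if fmt == "json":
            cb = cobra.io.load_json_model(path)
        elif fmt == "sbml":
            cb = cobra.io.read_sbml_model(path)
        else:
            raise ModelFormatError(f"unknown model format {fmt!r}")
    except (ModelFormatError, ModelConfigError):
        raise
    except Exception as exc:  # noqa: BLE001 - wrap parser errors uniformly
        raise ModelFormatError(f"failed to parse {path!r}: {exc}") from exc
    return from_cobra(cb)


def save_model(model: MetabolicModel, path: str) -> None:
    """Write the model as COBRA-JSON."""
    import cobra.io

    cobra.io.save_json_model(to_cobra(model), path)
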