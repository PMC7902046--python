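"""Metabolic-model data structures and constrained-optimization primitives.

The two solvers here are the substrate of every simulation in the package:

* :func:`solve_fba` — flux balance analysis, a linear program maximizing the
  biomass flux subject to steady-state mass balance ``S·V = 0`` and per-reaction
  bounds ``lb_j ≤ V_j ≤ ub_j``.
* :func:`solve_moma` — minimization of metabolic adjustment, a strictly convex
  quadratic program finding the feasible flux vector closest (L2) to a
  reference distribution under perturbed bounds.

FBA optima are generically non-unique.  To make every downstream quantity
(omics tables, batch trajectories, design productions) reproducible, FBA here
fixes the objective at its LP optimum and then minimizes the L2 norm of the
flux vector as a secondary objective, which selects a unique flux vector.

Sign convention: a negative exchange flux is uptake, a positive one secretion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

logger = logging.getLogger(__name__)

#: feasibility tolerance for bound/mass-balance checks (solver default scale)
FEASIBILITY_TOL = 1e-9
#: optimality tolerance for LP/QP termination
OPTIMALITY_TOL = 1e-8


class ModelFormatError(ValueError):
    """A model file could not be parsed into a valid model."""


class ModelConfigError(ValueError):
    """A structurally parseable model is missing required configuration."""


@dataclass
class MetabolicModel:
    """Stoichiometric model: S matrix, bounds, objective, and annotations.

    Parameters
    ----------
    metabolite_ids, reaction_ids
        Unique identifiers indexing the rows / columns of ``S``.
    S
        Stoichiometric matrix, ``m`` metabolites × ``n`` reactions.
    lb, ub
        Per-reaction flux bounds in mmol/gDW/h.
    objective_id
        Identifier of the biomass reaction to be maximized.
    exchange_map
        Metabolite id → exchange-reaction id, for boundary metabolites.
    feature_map
        Reaction id → (protein id, transcript id), used to label omics rows.
    metabolite_measurement_ids
        Metabolite id → typed measurement id (e.g. a PubChem ``CID:...``).
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    objective_id: str
    exchange_map: dict[str, str] = field(default_factory=dict)
    feature_map: dict[str, tuple[str, str]] = field(default_factory=dict)
    metabolite_measurement_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self.validate()
        self._rxn_index = {r: j for j, r in enumerate(self.reaction_ids)}
        self._met_index = {m: i for i, m in enumerate(self.metabolite_ids)}

    # -- structure ---------------------------------------------------------

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def reaction_index(self, rxn_id: str) -> int:
        return self._rxn_index[rxn_id]

    def metabolite_index(self, met_id: str) -> int:
        return self._met_index[met_id]

    @property
    def objective_vector(self) -> np.ndarray:
        c = np.zeros(self.n_reactions)
        c[self.reaction_index(self.objective_id)] = 1.0
        return c

    def validate(self) -> None:
        m, n = len(self.metabolite_ids), len(self.reaction_ids)
        if self.S.shape != (m, n):
            raise ModelFormatError(
                f"S has shape {self.S.shape}, expected ({m}, {n})"
            )
        if len(set(self.reaction_ids)) != n:
            raise ModelFormatError("reaction ids are not unique")
        if len(set(self.metabolite_ids)) != m:
            raise ModelFormatError("metabolite ids are not unique")
        if self.lb.shape != (n,) or self.ub.shape != (n,):
            raise ModelFormatError("bound vectors do not match reaction count")
        bad = np.nonzero(self.lb > self.ub)[0]
        if bad.size:
            names = [self.reaction_ids[j] for j in bad]
            raise ModelFormatError(f"lb > ub for reactions {names}")
        if self.objective_id not in self.reaction_ids:
            raise ModelConfigError(
                f"objective reaction {self.objective_id!r} not in model"
            )
        for met, rxn in self.exchange_map.items():
            if rxn not in self.reaction_ids:
                raise ModelFormatError(f"exchange reaction {rxn!r} unknown")
            col = self.S[:, self.reaction_ids.index(rxn)]
            if np.count_nonzero(col) != 1:
                raise ModelFormatError(
                    f"exchange reaction {rxn!r} must touch exactly one metabolite"
                )
            if met not in self.metabolite_ids:
                raise ModelFormatError(f"exchange metabolite {met!r} unknown")

    def detect_exchanges(self) -> dict[str, str]:
        """Exchange reactions found structurally: single nonzero S entry."""
        found: dict[str, str] = {}
        for j, rxn in enumerate(self.reaction_ids):
            nz = np.nonzero(self.S[:, j])[0]
            if nz.size == 1:
                found[self.metabolite_ids[nz[0]]] = rxn
        return found


@dataclass
class FluxState:
    """One solved flux vector (an LP/QP solution) at one time point."""

    fluxes: dict[str, float]
    objective_value: float
    status: str  # "optimal" | "infeasible" | "unbounded" | "error"
    message: str = ""

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def vector(self, model: MetabolicModel) -> np.ndarray:
        return np.array([self.fluxes[r] for r in model.reaction_ids])

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


class BoundOverride(dict):
    """Reaction id → ``(lb, ub)`` replacement pair.

    Equality constraints (a flux fixed to a value, e.g. a knockout) are
    encoded as ``lb == ub``.
    """

    def validate(self, model: MetabolicModel) -> None:
        for rxn, (lo, hi) in self.items():
            if rxn not in model.reaction_ids:
                raise KeyError(f"override references unknown reaction {rxn!r}")
            if lo > hi:
                raise ValueError(f"override lb > ub for {rxn!r}: {lo} > {hi}")

    def apply(self, model: MetabolicModel) -> tuple[np.ndarray, np.ndarray]:
        """Return (lb, ub) copies with the overrides applied."""
        self.validate(model)
        lb, ub = model.lb.copy(), model.ub.copy()
        for rxn, (lo, hi) in self.items():
            j = model.reaction_index(rxn)
            lb[j], ub[j] = lo, hi
        return lb, ub


# -- quadratic programming --------------------------------------------------


def _box_eq_qp(
    A: np.ndarray,
    b: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    target: np.ndarray,
    max_iter: int = 300,
) -> np.ndarray:
    """Minimize ``||x - target||²`` s.t. ``A x = b`` and ``lb ≤ x ≤ ub``.

    Primal active-set iteration on the bound constraints.  The equality
    system is kept in the KKT solve at every step (via least squares, so
    redundant mass-balance rows are harmless); bounds enter and leave a
    working set by most-violated / most-negative-multiplier rules, which is
    deterministic.  Bounds with ``lb == ub`` are permanently active.

    The caller must have verified feasibility (e.g. with a phase-1 LP);
    a non-convergent iteration raises ``RuntimeError``.
    """
    n = A.shape[1]
    lb = np.asarray(lb, float)
    ub = np.asarray(ub, float)
    target = np.asarray(target, float)

    # working set: index -> fixed value; sign +1 upper, -1 lower, 0 permanent
    permanent = np.nonzero(lb == ub)[0]
    active: dict[int, tuple[float, int]] = {int(j): (lb[j], 0) for j in permanent}

    for it in range(max_iter):
        free = np.array(
            [j for j in range(n) if j not in active], dtype=int
        )
        x = np.zeros(n)
        for j, (val, _) in active.items():
            x[j] = val
        if free.size:
            A_f = A[:, free]
            rhs = b - A @ x  # fixed-variable contribution moved to the rhs
            # KKT: x_f = t_f - A_f^T mu ;  A_f A_f^T mu = A_f t_f - rhs
            t_f = target[free]
            G = A_f @ A_f.T
            g = A_f @ t_f - rhs
            mu = np.linalg.lstsq(G, g, rcond=None)[0]
            x[free] = t_f - A_f.T @ mu
        else:
            # all variables fixed: recover equality multipliers for the check
            mu = np.linalg.lstsq(A.T, -(x - target), rcond=None)[0]

        scale = 1.0 + np.abs(x).max(initial=0.0)
        # primal feasibility of the bounds on the free variables
        viol_lo = lb - x
        viol_hi = x - ub
        for j in active:
            viol_lo[j] = viol_hi[j] = -np.inf
        worst = max(viol_lo.max(initial=-np.inf), viol_hi.max(initial=-np.inf))
        if worst > FEASIBILITY_TOL * scale:
            # most-violated rule; smallest-index (Bland-style) after many
            # iterations to break potential cycles on degenerate instances
            if it > max_iter // 2:
                j = int(
                    min(
                        np.nonzero(
                            np.maximum(viol_lo, viol_hi) > FEASIBILITY_TOL * scale
                        )[0]
                    )
                )
                active[j] = (lb[j], -1) if viol_lo[j] >= viol_hi[j] else (ub[j], +1)
            elif viol_lo.max(initial=-np.inf) >= viol_hi.max(initial=-np.inf):
                j = int(np.argmax(viol_lo))
                active[j] = (lb[j], -1)
            else:
                j = int(np.argmax(viol_hi))
                active[j] = (ub[j], +1)
            continue

        # dual feasibility of the working bounds (skip permanent ones)
        y = 2.0 * mu  # equality multipliers; gradient is 2(x - target)
        grad_like = 2.0 * (x - target) + A.T @ y
        worst_j, worst_lam = -1, -OPTIMALITY_TOL * scale
        for j, (_, sgn) in active.items():
            if sgn == 0:
                continue
            lam = -sgn * grad_like[j]
            if lam < worst_lam:
                worst_lam, worst_j = lam, j
        if worst_j >= 0:
            del active[worst_j]
            continue
        return x

    raise RuntimeError("active-set QP did not converge")


def _qp_fallback(
    A: np.ndarray,
    b: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    target: np.ndarray,
) -> np.ndarray:
    """Slow-but-robust QP fallback (interior trust-region) for the rare
    degenerate instances the active set cannot finish."""
    from scipy.optimize import Bounds, LinearConstraint, minimize

    n = A.shape[1]
    x0 = np.clip(target, lb, ub)
    res = minimize(
        lambda x: float(((x - target) ** 2).sum()),
        x0,
        jac=lambda x: 2.0 * (x - target),
        hess=lambda x: 2.0 * np.eye(n),
        method="trust-constr",
        constraints=[LinearConstraint(A, b, b)],
        bounds=Bounds(lb, ub),
        options={"xtol": 1e-12, "gtol": 1e-10, "maxiter": 2000, "verbose": 0},
    )
    return np.asarray(res.x)


def _solve_qp(
    A: np.ndarray,
    b: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    target: np.ndarray,
) -> np.ndarray:
    try:
        return _box_eq_qp(A, b, lb, ub, target)
    except RuntimeError:
        logger.debug("active-set QP fell back to trust-constr")
        return _qp_fallback(A, b, lb, ub, target)


def _check_feasible(
    S: np.ndarray, lb: np.ndarray, ub: np.ndarray
) -> bool:
    res = linprog(
        c=np.zeros(S.shape[1]),
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    return res.status == 0


def _as_flux_state(
    model: MetabolicModel, x: np.ndarray, objective_value: float
) -> FluxState:
    fluxes = {r: float(x[j]) for j, r in enumerate(model.reaction_ids)}
    return FluxState(fluxes=fluxes, objective_value=objective_value, status="optimal")


def solve_fba(
    model: MetabolicModel,
    overrides: BoundOverride | None = None,
) -> FluxState:
    """Flux balance analysis with a deterministic minimum-L2-norm tie-break.

    Maximizes the objective (biomass) flux subject to ``S·V = 0`` and the
    override-modified bounds.  Among the (generally many) alternate optima the
    returned flux vector is the unique one of minimal Euclidean norm, obtained
    by fixing the objective at its LP optimum and solving a secondary QP.
    """
    overrides = overrides if overrides is not None else BoundOverride()
    lb, ub = overrides.apply(model)
    c = model.objective_vector
    res = linprog(
        c=-c,
        A_eq=model.S,
        b_eq=np.zeros(model.n_metabolites),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if res.status == 2:
        return FluxState({}, float("nan"), "infeasible", res.message)
    if res.status == 3:
        j_unb = [
            model.reaction_ids[j]
            for j in range(model.n_reactions)
            if np.isinf(lb[j]) or np.isinf(ub[j])
        ]
        return FluxState(
            {},
            float("nan"),
            "unbounded",
            f"objective unbounded; reactions with infinite bounds: {j_unb}",
        )
    if res.status != 0:
        return FluxState({}, float("nan"), "error", res.message)

    opt = float(-res.fun)
    # secondary objective: min ||V||^2 at fixed optimum -> unique flux vector
    A_eq = np.vstack([model.S, c])
    b_eq = np.append(np.zeros(model.n_metabolites), opt)
    x = _solve_qp(A_eq, b_eq, lb, ub, target=np.zeros(model.n_reactions))
    return _as_flux_state(model, x, opt)


def solve_moma(
    model: MetabolicModel,
    reference: FluxState,
    overrides: BoundOverride | None = None,
) -> FluxState:
    """Minimization of metabolic adjustment against a reference flux vector.

    Minimizes ``Σ_j (V_j − V_ref,j)²`` subject to ``S·V = 0`` and the
    override-modified bounds, modelling a perturbed (engineered) strain whose
    fluxes stay as close as possible to the unperturbed reference.  The
    reported ``objective_value`` is the biomass flux of the solution.
    """
    if not reference.optimal:
        raise ValueError("MOMA reference must be a solved flux state")
    overrides = overrides if overrides is not None else BoundOverride()
    lb, ub = overrides.apply(model)
    if not _check_feasible(model.S, lb, ub):
        return FluxState({}, float("nan"), "infeasible", "no feasible flux vector")
    v_ref = reference.vector(model)
    x = _solve_qp(
        model.S,
        np.zeros(model.n_metabolites),
        lb,
        ub,
        target=v_ref,
    )
    mu = float(x[model.reaction_index(model.objective_id)])
    return _as_flux_state(model, x, mu)


def write_fluxes_tsv(flux: FluxState, path) -> None:
    """Write one flux vector as a 2-column TSV (reaction id, flux)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("reaction_id\tflux\n")
        for rxn, v in flux.fluxes.items():
            fh.write(f"{rxn}\t{v:.10g}\n")
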