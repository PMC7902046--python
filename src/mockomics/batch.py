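"""Batch-culture time series by repeated FBA / MOMA.

A batch culture is simulated on a fixed time grid: at every time point an FBA
problem (or, for an engineered strain, a MOMA problem against the wild-type
flux vector of the same time point) is solved, the cell density is advanced
exponentially, and every extracellular concentration is updated from its
exchange flux.  With growth rate ``μ`` over a step ``Δt`` the cell density
obeys ``[cell]_new = [cell]·exp(μΔt)`` and each extracellular metabolite is
updated by

    [met]_new = [met]_old + v_EX · Δ[cell]/μ,      Δ[cell] = [cell](e^{μΔt}−1)

the exponential refinement of the linear rule ``[met]_old + v_EX·Δt·[cell]``
(the two coincide as ``μ → 0``, which is also the fallback used when ``μ`` is
numerically zero).  The loop ends when the primary carbon source is exhausted,
growth stops, or the time horizon is reached.

Uptake capping: at each step the lower bound of every exchange reaction is
raised so that no concentration can be driven negative within the step; since
the cap depends on ``μ`` the solve is iterated a few times until the cap and
the growth rate are consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import BoundOverride, FluxState, MetabolicModel, solve_fba, solve_moma


class SimulationError(RuntimeError):
    """The batch simulation could not start or proceed."""


@dataclass
class BatchConditions:
    """Initial state and grid of a batch culture.

    Concentrations are mM, cell density gDW/L, times hours.  Metabolites not
    listed in ``initial_concentrations`` start at 0 mM (products accumulate
    from zero).
    """

    initial_concentrations: dict[str, float]
    initial_cell_density: float = 0.01
    dt: float = 1.0
    max_time: float = 24.0
    primary_substrate: str = "glc_e"
    exhaustion_threshold: float = 1e-3  # mM
    mu_min: float = 1e-6  # 1/h

    def validate(self, model: MetabolicModel) -> None:
        if self.dt <= 0:
            raise SimulationError("timestep must be positive")
        if self.max_time <= 0:
            raise SimulationError("max_time must be positive")
        if self.initial_cell_density <= 0:
            raise SimulationError("initial cell density must be positive")
        for met, conc in self.initial_concentrations.items():
            if conc < 0:
                raise SimulationError(f"negative initial concentration for {met}")
            if met not in model.exchange_map:
                raise SimulationError(f"{met!r} has no exchange reaction")
        if self.primary_substrate not in model.exchange_map:
            raise SimulationError(
                f"primary substrate {self.primary_substrate!r} has no exchange reaction"
            )


@dataclass
class BatchTimeSeries:
    """Result of a batch simulation: one state per recorded time point."""

    times: np.ndarray  # h, strictly increasing
    cell_density: np.ndarray  # gDW/L
    concentrations: dict[str, np.ndarray]  # met id -> mM per time
    fluxes: list[FluxState]
    growth_rates: np.ndarray  # 1/h
    conditions: BatchConditions
    lethal: bool = False
    lethal_from: int | None = None

    def __len__(self) -> int:
        return len(self.times)

    def final_concentration(self, met_id: str) -> float:
        return float(self.concentrations[met_id][-1])


def linear_concentration_update(
    conc_old: float, v_exchange: float, dt_times_cell: float
) -> float:
    """Linear extracellular update: ``[met]_old + v_EX · Δt·[cell]``.

    ``v_exchange`` in mmol/gDW/h (negative = uptake), ``dt_times_cell`` in
    gDW·h/L; the product is a concentration change in mM.
    """
    return conc_old + v_exchange * dt_times_cell


def _conversion_factor(cell: float, mu: float, dt: float, mu_min: float) -> float:
    """Δ[cell]/μ — the factor turning a flux into a concentration change.

    Falls back to the linear ``Δt·[cell]`` when growth is numerically zero
    (the μ→0 limit of the exponential form).
    """
    if mu > mu_min:
        return cell * (math.exp(mu * dt) - 1.0) / mu
    return cell * dt


def _uptake_caps(
    model: MetabolicModel,
    conc: dict[str, float],
    factor: float,
    base: BoundOverride,
) -> BoundOverride:
    """Raise exchange lower bounds so no concentration can go negative."""
    caps = BoundOverride(base)
    for met, rxn in model.exchange_map.items():
        j = model.reaction_index(rxn)
        lb, ub = caps.get(rxn, (model.lb[j], model.ub[j]))
        max_uptake = conc.get(met, 0.0) / factor if factor > 0 else 0.0
        new_lb = max(lb, -max_uptake)
        caps[rxn] = (new_lb, max(new_lb, ub) if new_lb > ub else ub)
    return caps


def _solve_step(
    model: MetabolicModel,
    conc: dict[str, float],
    cell: float,
    dt: float,
    mu_min: float,
    mu_guess: float,
    base_overrides: BoundOverride,
    reference: FluxState | None,
    max_cap_iter: int = 25,
) -> tuple[FluxState, float]:
    """Solve one time step with self-consistent uptake caps.

    Returns the flux state and the converged growth rate.  ``reference`` is
    None for FBA (wild type) or the wild-type flux vector for MOMA.
    """
    mu = max(mu_guess, 0.0)
    flux = FluxState({}, float("nan"), "error")
    for _ in range(max_cap_iter):
        factor = _conversion_factor(cell, mu, dt, mu_min)
        caps = _uptake_caps(model, conc, factor, base_overrides)
        if reference is None:
            flux = solve_fba(model, caps)
        else:
            flux = solve_moma(model, reference, caps)
        if not flux.optimal:
            return flux, 0.0
        mu_new = flux.fluxes[model.objective_id]
        if abs(mu_new - mu) <= 1e-9 * (1.0 + abs(mu)):
            return flux, mu_new
        mu = mu_new
    return flux, mu


def _run_batch(
    model: MetabolicModel,
    conditions: BatchConditions,
    overrides_for_step,
    reference_for_step,
) -> BatchTimeSeries:
    conditions.validate(model)
    dt = conditions.dt
    n_steps = int(round(conditions.max_time / dt))
    conc = {
        met: float(conditions.initial_concentrations.get(met, 0.0))
        for met in model.exchange_map
    }
    cell = conditions.initial_cell_density

    times: list[float] = []
    cells: list[float] = []
    concs: dict[str, list[float]] = {met: [] for met in conc}
    fluxes: list[FluxState] = []
    mus: list[float] = []
    lethal = False
    lethal_from: int | None = None

    zero_flux = FluxState(
        {r: 0.0 for r in model.reaction_ids}, 0.0, "optimal", "no flux"
    )
    mu_prev = 0.0
    for k in range(n_steps + 1):
        t = k * dt
        exhausted = (
            conc[conditions.primary_substrate] < conditions.exhaustion_threshold
        )
        base = overrides_for_step(k)
        reference = reference_for_step(k)
        if exhausted:
            # carbon source gone: terminal point with zero flux, zero growth
            flux, mu = zero_flux, 0.0
        elif base is None or (reference is not None and not reference.optimal):
            flux, mu = FluxState({}, float("nan"), "infeasible"), 0.0
        else:
            flux, mu = _solve_step(
                model, conc, cell, dt, conditions.mu_min, mu_prev, base, reference
            )

        if not flux.optimal:
            if reference is None:
                if k == 0:
                    raise SimulationError(
                        f"infeasible at t=0 under conditions {conditions}"
                    )
                # wild type starves (residual substrate cannot sustain the
                # model's constitutive demands): terminal point, not lethal
                flux, mu = zero_flux, 0.0
            else:
                # lethal design: record an all-zero flux vector and stop
                lethal = True
                lethal_from = k
                flux, mu = zero_flux, 0.0

        times.append(t)
        cells.append(cell)
        for met in conc:
            concs[met].append(conc[met])
        fluxes.append(flux)
        mus.append(mu)

        if (
            lethal
            or exhausted
            or mu <= conditions.mu_min
            or t >= conditions.max_time
        ):
            break

        factor = _conversion_factor(cell, mu, dt, conditions.mu_min)
        for met, rxn in model.exchange_map.items():
            v = flux.fluxes[rxn]
            conc[met] = max(0.0, conc[met] + v * factor)
        cell = cell * math.exp(mu * dt) if mu > conditions.mu_min else cell
        mu_prev = mu

    return BatchTimeSeries(
        times=np.array(times),
        cell_density=np.array(cells),
        concentrations={m: np.array(v) for m, v in concs.items()},
        fluxes=fluxes,
        growth_rates=np.array(mus),
        conditions=conditions,
        lethal=lethal,
        lethal_from=lethal_from,
    )


def run_wt_batch(
    model: MetabolicModel, conditions: BatchConditions
) -> BatchTimeSeries:
    """Simulate the unmodified (wild-type) strain by stepwise FBA."""
    empty = BoundOverride()
    return _run_batch(
        model,
        conditions,
        overrides_for_step=lambda k: empty,
        reference_for_step=lambda k: None,
    )


def run_designed_batch(
    model: MetabolicModel,
    wt_series: BatchTimeSeries,
    design_overrides_per_time: list[BoundOverride],
    overlay_wt: bool = False,
) -> BatchTimeSeries:
    """Simulate an engineered strain by stepwise MOMA against the WT series.

    At each time point of the wild-type grid, MOMA is solved against the
    wild-type flux vector of that time point under the design's bound
    overrides.  By default the engineered strain's cell density and
    concentrations are propagated independently from its own MOMA fluxes (a
    design that slows growth also slows substrate depletion); with
    ``overlay_wt=True`` the wild-type trajectory of cell density and
    concentrations is kept and only the fluxes are recomputed, the other
    reading of a per-time-point MOMA overlay.

    A MOMA-infeasible step marks the design lethal: an all-zero flux vector
    is recorded from that point on and the series is flagged.
    """
    n = len(wt_series)
    if len(design_overrides_per_time) != n:
        raise ValueError(
            "need one override set per wild-type time point "
            f"({len(design_overrides_per_time)} != {n})"
        )

    if overlay_wt:
        fluxes: list[FluxState] = []
        mus = []
        lethal = False
        lethal_from: int | None = None
        for k in range(n):
            flux = solve_moma(model, wt_series.fluxes[k], design_overrides_per_time[k])
            if not flux.optimal:
                lethal, lethal_from = True, lethal_from if lethal else k
                flux = FluxState(
                    {r: 0.0 for r in model.reaction_ids}, 0.0, "optimal",
                    "lethal: recorded as zero flux",
                )
            fluxes.append(flux)
            mus.append(flux.fluxes[model.objective_id])
        return BatchTimeSeries(
            times=wt_series.times.copy(),
            cell_density=wt_series.cell_density.copy(),
            concentrations={m: v.copy() for m, v in wt_series.concentrations.items()},
            fluxes=fluxes,
            growth_rates=np.array(mus),
            conditions=wt_series.conditions,
            lethal=lethal,
            lethal_from=lethal_from,
        )

    def overrides_for_step(k: int) -> BoundOverride | None:
        if k >= n:
            return None
        return design_overrides_per_time[k]

    def reference_for_step(k: int) -> FluxState | None:
        return wt_series.fluxes[min(k, n - 1)]

    # same grid as the wild type: the horizon is the wild-type series' end
    conditions = BatchConditions(
        initial_concentrations=dict(wt_series.conditions.initial_concentrations),
        initial_cell_density=wt_series.conditions.initial_cell_density,
        dt=wt_series.conditions.dt,
        max_time=float(wt_series.times[-1]) if n > 1 else wt_series.conditions.dt,
        primary_substrate=wt_series.conditions.primary_substrate,
        exhaustion_threshold=wt_series.conditions.exhaustion_threshold,
        mu_min=wt_series.conditions.mu_min,
    )
    return _run_batch(model, conditions, overrides_for_step, reference_for_step)
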