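"""Batch-culture simulation: update rules, invariants, engineered strains."""

import numpy as np
import pytest

from mockomics import (
    BatchConditions,
    BoundOverride,
    MetabolicModel,
    linear_concentration_update,
    run_designed_batch,
    run_wt_batch,
)
from mockomics.batch import SimulationError

#: carbon content of the toy model's exchanged metabolites
TOY_CARBON = {
    "glc_e": 6, "for_e": 1, "ac_e": 2, "pyr_e": 3,
    "oaa_e": 3, "mal_e": 3, "ipre_e": 2, "nh4_e": 0,
}


def fixed_yield_model(q=10.0, yield_=0.05):
    """Single-pathway model with constant uptake q and biomass yield Y:
    the batch obeys the two-ODE system dX/dt = Y q X, ds/dt = -q X."""
    return MetabolicModel(
        metabolite_ids=["s_e", "x_c"],
        reaction_ids=["EX_s", "UPT", "BIOMASS"],
        S=np.array([[-1.0, -1.0, 0.0], [0.0, 1.0, -1.0 / yield_]]),
        lb=np.array([-q, 0.0, 0.0]),
        ub=np.array([1000.0, 1000.0, 1000.0]),
        objective_id="BIOMASS",
        exchange_map={"s_e": "EX_s"},
    )


class TestUpdateRules:
    def test_linear_update_arithmetic(self):
        # 22 mM glucose, uptake -15 mmol/gDW/h, Δt·[cell] = 0.1 gDW·h/L
        assert linear_concentration_update(22.0, -15.0, 0.1) == pytest.approx(20.5)

    def test_exhausted_at_start_gives_single_point(self, toy_model):
        conditions = BatchConditions(
            initial_concentrations={"glc_e": 0.0, "nh4_e": 18.0},
            primary_substrate="glc_e",
        )
        series = run_wt_batch(toy_model, conditions)
        assert len(series) == 1
        assert series.growth_rates[0] == 0.0
        assert not series.lethal

    def test_matches_closed_form_exponential_solution(self):
        q, yield_ = 10.0, 0.05
        mu = q * yield_
        model = fixed_yield_model(q, yield_)
        x0, s0 = 0.01, 20.0
        conditions = BatchConditions(
            initial_concentrations={"s_e": s0},
            initial_cell_density=x0,
            dt=0.1,
            max_time=40.0,
            primary_substrate="s_e",
        )
        series = run_wt_batch(model, conditions)
        # closed form: X(t) = X0 e^{μt}, s(t) = s0 - (q/μ)(X(t) - X0)
        for k, t in enumerate(series.times[:-1]):  # last point may be capped
            x_exact = x0 * np.exp(mu * t)
            s_exact = s0 - (q / mu) * (x_exact - x0)
            assert series.cell_density[k] == pytest.approx(x_exact, rel=0.02)
            assert series.concentrations["s_e"][k] == pytest.approx(
                max(s_exact, 0.0), rel=0.02, abs=0.02
            )

    def test_invalid_conditions_rejected(self, toy_model):
        with pytest.raises(SimulationError):
            run_wt_batch(
                toy_model,
                BatchConditions({"glc_e": 22.0}, dt=-1.0),
            )
        with pytest.raises(SimulationError):
            run_wt_batch(
                toy_model,
                BatchConditions({"glc_e": 22.0}, primary_substrate="not_a_met"),
            )


class TestSeriesInvariants:
    def test_wild_type_series(self, toy_model, wt_series):
        times = wt_series.times
        assert (np.diff(times) > 0).all()
        glc = wt_series.concentrations["glc_e"]
        assert (np.diff(glc) <= 1e-9).all(), "substrate must not increase"
        for values in wt_series.concentrations.values():
            assert (values >= 0).all()
        growing = wt_series.growth_rates[:-1] > 0
        assert (np.diff(wt_series.cell_density)[growing] > 0).all()
        assert not wt_series.lethal

    def test_carbon_accounting(self, toy_model, wt_series):
        for flux in wt_series.fluxes:
            consumed = 0.0
            excreted = 0.0
            for met, rxn in toy_model.exchange_map.items():
                v = flux.fluxes[rxn]
                carbon = TOY_CARBON[met]
                if v < 0:
                    consumed += -v * carbon
                else:
                    excreted += v * carbon
            assert consumed >= excreted - 1e-6

    def test_grid_refinement_consistency(self, toy_model):
        finals = []
        for dt in (1.0, 0.5):
            conditions = BatchConditions(
                initial_concentrations={"glc_e": 22.0, "nh4_e": 18.0},
                dt=dt,
                primary_substrate="glc_e",
            )
            series = run_wt_batch(toy_model, conditions)
            finals.append(series.final_concentration("ipre_e"))
        assert finals[1] == pytest.approx(finals[0], rel=0.05)


class TestDesignedBatch:
    def test_empty_overrides_reproduce_wild_type(self, toy_model, wt_series):
        empty = [BoundOverride() for _ in range(len(wt_series))]
        series = run_designed_batch(toy_model, wt_series, empty)
        assert len(series) == len(wt_series)
        np.testing.assert_allclose(series.times, wt_series.times)
        np.testing.assert_allclose(
            series.cell_density, wt_series.cell_density, rtol=1e-6
        )
        for met in wt_series.concentrations:
            np.testing.assert_allclose(
                series.concentrations[met],
                wt_series.concentrations[met],
                rtol=1e-6, atol=1e-9,
            )

    def test_blocked_uptake_is_lethal(self, toy_model, wt_series):
        blocked = [
            BoundOverride({"GLCup": (0.0, 0.0)}) for _ in range(len(wt_series))
        ]
        series = run_designed_batch(toy_model, wt_series, blocked)
        assert series.lethal and series.lethal_from == 0
        assert series.final_concentration("ipre_e") == 0.0
        assert (series.growth_rates == 0).all()

    def test_override_count_mismatch_rejected(self, toy_model, wt_series):
        with pytest.raises(ValueError, match="per wild-type time point"):
            run_designed_batch(toy_model, wt_series, [BoundOverride()])

    def test_knockout_matches_stepwise_qp_oracle(self, toy_model):
        """Independent propagation oracle: same grid, SLSQP per time point."""
        from scipy.optimize import minimize

        conditions = BatchConditions(
            initial_concentrations={"glc_e": 50.0, "nh4_e": 50.0},
            dt=1.0,
            max_time=3.0,  # substrate plentiful: uptake caps never bind
            primary_substrate="glc_e",
        )
        wt = run_wt_batch(toy_model, conditions)
        overrides = [BoundOverride({"PFL": (0.0, 0.0)}) for _ in range(len(wt))]
        series = run_designed_batch(toy_model, wt, overrides)

        S = toy_model.S
        n = toy_model.n_reactions
        j_bio = toy_model.reaction_index(toy_model.objective_id)
        j_pfl = toy_model.reaction_index("PFL")
        cell, conc = conditions.initial_cell_density, {
            m: conditions.initial_concentrations.get(m, 0.0)
            for m in toy_model.exchange_map
        }
        for k in range(len(wt)):
            ref = wt.fluxes[k].vector(toy_model)
            lb, ub = toy_model.lb.copy(), toy_model.ub.copy()
            lb[j_pfl] = ub[j_pfl] = 0.0
            res = minimize(
                lambda v: ((v - ref) ** 2).sum(),
                np.clip(ref, lb, ub),
                jac=lambda v: 2 * (v - ref),
                constraints=[{"type": "eq", "fun": lambda v: S @ v,
                              "jac": lambda v: S}],
                bounds=list(zip(lb, ub)),
                method="SLSQP",
                options={"maxiter": 500, "ftol": 1e-12},
            )
            assert res.success
            mu = res.x[j_bio]
            assert series.growth_rates[k] == pytest.approx(mu, abs=1e-4)
            if k < len(series) - 1:
                factor = cell * (np.exp(mu * 1.0) - 1.0) / mu
                for met, rxn in toy_model.exchange_map.items():
                    conc[met] += res.x[toy_model.reaction_index(rxn)] * factor
                cell *= np.exp(mu * 1.0)
        assert series.final_concentration("ipre_e") == pytest.approx(
            conc["ipre_e"], rel=1e-3
        )

    def test_overlay_mode_keeps_wild_type_trajectory(self, toy_model, wt_series):
        overrides = [
            BoundOverride({"PFL": (0.0, 0.0)}) for _ in range(len(wt_series))
        ]
        series = run_designed_batch(
            toy_model, wt_series, overrides, overlay_wt=True
        )
        np.testing.assert_allclose(series.cell_density, wt_series.cell_density)
        assert all(f.fluxes["PFL"] == 0.0 for f in series.fluxes)
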