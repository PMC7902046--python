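import numpy as np
import pytest

from mockomics import (
    MetabolicModel,
    default_conditions,
    make_toy_model,
    run_wt_batch,
)


@pytest.fixture(scope="session")
def toy_model():
    return make_toy_model()


@pytest.fixture(scope="session")
def wt_series(toy_model):
    return run_wt_batch(toy_model, default_conditions())


@pytest.fixture()
def chain_model():
    """3-reaction chain: uptake (<= 10) -> conversion -> biomass drain."""
    return MetabolicModel(
        metabolite_ids=["s_e", "x_c"],
        reaction_ids=["EX_s", "CONV", "BIOMASS"],
        S=np.array([[-1.0, -1.0, 0.0], [0.0, 1.0, -1.0]]),
        lb=np.array([-10.0, 0.0, 0.0]),
        ub=np.array([1000.0, 1000.0, 1000.0]),
        objective_id="BIOMASS",
        exchange_map={"s_e": "EX_s"},
    )
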