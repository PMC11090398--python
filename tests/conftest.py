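import numpy as np
import pytest

import dynsrm
from dynsrm import SimDesign
from dynsrm.draws import PosteriorDraws
from dynsrm.roles import undirected_dyads


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_ordinal_data():
    params = dynsrm.headline_params("ordinal")
    design = SimDesign(K=8, seed=42, duration_p_max=0.0, duration_lo=3, duration_hi=6)
    return params, dynsrm.simulate_dataset(params, design)


@pytest.fixture(scope="session")
def tiny_continuous_data():
    params = dynsrm.headline_params("continuous")
    design = SimDesign(K=8, seed=43, duration_p_max=0.0, duration_lo=3, duration_hi=6)
    return params, dynsrm.simulate_dataset(params, design)


def synthetic_draws(arrays: dict[str, np.ndarray], roles=("M", "F", "S1", "S2")) -> PosteriorDraws:
    """Assemble a PosteriorDraws from raw per-parameter chains (tests only)."""
    values = {k: np.atleast_2d(np.asarray(v, float)) for k, v in arrays.items()}
    meta = {
        "roles": list(roles),
        "undirected": [str(u) for u in undirected_dyads(roles)],
        "response_kind": "continuous",
        "dynamics": "ar_crosslag",
    }
    return PosteriorDraws(values=values, meta=meta)
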