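import numpy as np
import pytest

from misbind.core import Condition
from misbind.forward import ModelParams, simulate_dataset
from misbind.taskgen import DesignSpec, TaskGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def geometry():
    return TaskGeometry()


@pytest.fixture(scope="session")
def default_params():
    return ModelParams.default()


@pytest.fixture(scope="session")
def rich_params():
    """Parameters with every error pathway clearly active."""
    return ModelParams(
        kappa_colour=6.0,
        kappa_location=8.0,
        p_swap=0.2,
        p_cyclic_swap=0.08,
        g_feature=0.15,
        g_object=0.1,
        g_feat_swap_non=0.12,
        g_feat_swap_swp=0.3,
        g_obj_swap_non=0.06,
        g_obj_swap_swp=0.25,
        g_feat_cyclic=0.18,
        g_obj_cyclic=0.09,
        order_weights=(0.3, 0.2, 0.15, 0.15, 0.1, 0.1),
    )


def random_params(rng: np.random.Generator) -> ModelParams:
    """A random valid parameter set covering the whole support."""
    p_swap, p_cyc = rng.dirichlet((1.5, 1.0, 4.0))[:2]
    g = rng.uniform(0.02, 0.4, size=8)
    return ModelParams(
        kappa_colour=float(rng.uniform(0.5, 30.0)),
        kappa_location=float(rng.uniform(0.5, 30.0)),
        p_swap=float(p_swap),
        p_cyclic_swap=float(p_cyc),
        g_feature=float(g[0]),
        g_object=float(g[1]),
        g_feat_swap_non=float(g[2]),
        g_feat_swap_swp=float(g[3]),
        g_obj_swap_non=float(g[4]),
        g_obj_swap_swp=float(g[5]),
        g_feat_cyclic=float(g[6]),
        g_obj_cyclic=float(g[7]),
        order_weights=tuple(rng.dirichlet(np.ones(6))),
    )


@pytest.fixture(scope="session")
def mixed_dataset(rich_params):
    """Small simulated experiment over all four probe conditions."""
    params = {
        s: {g: rich_params for g in ("cued", "uncued_LC", "uncued_CL")}
        for s in range(3)
    }
    design = DesignSpec(n_subjects=3, trials_per_condition=12)
    return simulate_dataset(params, design, seed=99)


@pytest.fixture(scope="session")
def uncued_condition():
    return Condition("uncued_LC")
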