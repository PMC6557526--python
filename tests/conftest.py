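"""Shared fixtures: default geometry, parameter sets and protocols."""

import numpy as np
import pytest

import dmt1flux as dx


@pytest.fixture(scope="session")
def geometry():
    return dx.default_geometry()


@pytest.fixture(scope="session")
def switch_params():
    return dx.default_switch_parameters()


@pytest.fixture(scope="session")
def swing_params():
    return dx.default_swing_parameters()


@pytest.fixture(scope="session")
def protocol():
    return dx.default_protocol()


@pytest.fixture(scope="session")
def protocol_one():
    return dx.default_protocol(n_challenges=1)


@pytest.fixture(scope="session")
def switch_trajectory(geometry, switch_params, protocol):
    """Dense two-challenge switch-model run shared across read-only tests."""
    return dx.run_protocol("switch", switch_params, geometry, protocol, dt=0.05)


@pytest.fixture(scope="session")
def swing_trajectory(geometry, swing_params, protocol):
    """Dense two-challenge swing-model run shared across read-only tests."""
    return dx.run_protocol("swing", swing_params, geometry, protocol, dt=0.05)


@pytest.fixture(scope="session")
def clean_swing_dataset(geometry, swing_params, protocol_one):
    """Noise-free single-challenge swing dataset (end-to-end closure input)."""
    return dx.generate_uptake_dataset(
        "swing", swing_params, geometry, protocol_one,
        noise=dx.NoiseModel(cv=0.0, seed=1),
    )


def random_state(rng, model):
    """A random admissible ModelState for RHS property tests."""
    p = rng.dirichlet(np.ones(6))
    if model == "switch":
        p[4] += p[5]
        p[5] = 0.0
    return dx.ModelState(
        P=p,
        FeIN=float(rng.uniform(0.0, 5.0)),
        FeOUT=float(rng.uniform(0.0, 25.0)),
        mode=dx.Mode.ENDOCYTIC if model == "switch" else None,
        j=1,
        FeUP_history=(0.0,),
        FeCHG_history=(20.0,),
    )
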