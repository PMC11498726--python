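import numpy as np
import pytest

import sivs_ou as so


@pytest.fixture(scope="session")
def group1():
    """Low-transmission parameter set (extinct regime, R0 < 1)."""
    return so.fixture("group1")


@pytest.fixture(scope="session")
def group2():
    """High-transmission parameter set (persistent regime, R0 = 2)."""
    return so.fixture("group2")


@pytest.fixture(scope="session")
def group2_equilibrium(group2):
    return so.endemic_equilibrium(group2)


@pytest.fixture(scope="session")
def paper_init():
    """Common initial condition used in the simulation experiments."""
    return so.SivsState(S=0.04, I=0.8, V=0.03, m=-0.02)


def random_hurwitz_params(rng: np.random.Generator, n: int) -> list:
    """Draw n valid parameter sets with R0 > 1 and a Hurwitz linearization."""
    out = []
    while len(out) < n:
        p = dict(
            A=rng.uniform(0.1, 2.0),
            g=rng.uniform(0.1, 0.9),
            eta=rng.uniform(0.02, 0.5),
            p=rng.uniform(0.1, 1.0),
            beta=rng.uniform(0.2, 2.0),
            gamma=rng.uniform(0.0, 1.0),
            alpha=rng.uniform(0.01, 1.0),
            k=rng.uniform(0.05, 2.0),
            theta=rng.uniform(0.01, 0.3),
        )
        p["epsilon"] = rng.uniform(0.0, p["p"])  # lethality below vaccination rate
        params = so.ModelParams(**p)
        th = so.stochastic_thresholds(params)
        if th.R0S <= 1.0:
            continue
        lin = so.linearize(params)
        if so.characteristic_coefficients(lin).hurwitz:
            out.append(params)
    return out
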