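import math

import numpy as np
import pytest

from quiescence.cellmodel import CellModel, ResponseFunction, solve_steady_state
from quiescence.fixtures import make_fixture


@pytest.fixture(scope="session")
def fig4_model():
    return make_fixture("fig4")


@pytest.fixture(scope="session")
def fig4_ss(fig4_model):
    return solve_steady_state(fig4_model)


@pytest.fixture(scope="session")
def steep_model():
    return make_fixture("steep")


@pytest.fixture(scope="session")
def shallow_model():
    return make_fixture("shallow")


def random_valid_model(rng: np.random.Generator) -> CellModel:
    """A random model satisfying R0(0) < 1 < R0(1) and the monotonicity
    hypothesis, drawn from both regulatory families.

    g-regulated: constant beta1, increasing Hill G calibrated so that the
    steady state sits at a random Ebar.  beta1-regulated: constant G at the
    level that makes beta1(Ebar) = 1/2, increasing Hill beta1.
    """
    mu = float(rng.uniform(0.05, 0.6))
    em = math.exp(-mu)
    Ebar = float(rng.uniform(0.2, 0.8))
    n = float(rng.uniform(1.0, 6.0))
    theta = float(rng.uniform(0.0, 1.0))
    if rng.random() < 0.5:
        b1 = float(rng.uniform(0.05, 0.95)) / (2.0 * em)
        target = (1.0 - 2.0 * em * b1) * mu / (2.0 * em - 1.0)
        return CellModel(
            death_rate=mu,
            theta=theta,
            beta1=ResponseFunction("constant", (b1,)),
            G=ResponseFunction("hill_increasing", (2.0 * target, n, Ebar)),
        )
    g = (1.0 - em) * mu / (2.0 * em - 1.0)  # makes beta1(Ebar) = 1/2
    return CellModel(
        death_rate=mu,
        theta=theta,
        beta1=ResponseFunction("hill_increasing", (1.0, n, Ebar)),
        G=ResponseFunction("constant", (g,)),
    )
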