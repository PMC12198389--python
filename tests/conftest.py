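import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from mechpes.backends import BeadSpringFlex, MullerBrown, QuarticDoubleWell
from mechpes.optimize import OptimizationSettings, dimer_ts_search, minimize


@pytest.fixture(scope="session")
def qdw():
    return QuarticDoubleWell(a=1.0, b=2.0)


@pytest.fixture(scope="session")
def mb():
    return MullerBrown()

@pytest.fixture(scope="session")
def mb_oracle(mb):
    """Grid+Newton stationary points of the Müller–Brown surface."""
    from oracles import muller_brown_stationary_points

    def exy(v):
        return mb._energy(np.array([v[0], v[1], 0.0]))

    minima, saddles = muller_brown_stationary_points(exy)
    assert minima.shape[0] == 3 and saddles.shape[0] == 2
    return {"minima": minima, "saddles": saddles}


@pytest.fixture(scope="session")
def flex():
    return BeadSpringFlex()


@pytest.fixture(scope="session")
def tight_settings():
    return OptimizationSettings(gradient_convergence=1e-8)


@pytest.fixture(scope="session")
def flex_reactant(flex, tight_settings):
    point = minimize(flex.reference_reactant(), flex, tight_settings)
    assert point.converged
    return point


@pytest.fixture(scope="session")
def flex_ts(flex, tight_settings):
    point = dimer_ts_search(flex.reference_ts_guess(), flex, tight_settings)
    assert point.converged
    return point
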