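import numpy as np
import pytest

from kincontest.equilibrium import SolverOptions
from kincontest.game import FitnessFormulation
from kincontest.trials import GeneratingParams, TrialDesign

ALL_FORMULATIONS = list(FitnessFormulation)


@pytest.fixture(scope="session")
def fast_opts():
    """Solver options tuned for test speed; accuracy checks use defaults."""
    return SolverOptions(grid_points=401, restarts=4)


@pytest.fixture(scope="session")
def default_params():
    return GeneratingParams.default()


@pytest.fixture(scope="session")
def small_design():
    return TrialDesign(n_per_level=5)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
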