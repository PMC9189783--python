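import numpy as np
import pytest

from fermopt import datasets
from fermopt.doe import Factor, FactorSet


@pytest.fixture(scope="session")
def factors2():
    return FactorSet([Factor("a", 10.0, 20.0, "%"), Factor("b", 1.0, 3.0, "g/L")])


@pytest.fixture(scope="session")
def study_factors():
    """The five medium factors of the packaged 50-run design."""
    return datasets.ccrd_factors()


@pytest.fixture(scope="session")
def ccrd_runs():
    return datasets.load_fixture("ccrd_runs")


@pytest.fixture(scope="session")
def coded_runs(ccrd_runs, study_factors):
    X = ccrd_runs[datasets.CCRD_FACTOR_COLUMNS].to_numpy(float)
    return study_factors.code(X)


@pytest.fixture(scope="session")
def activity(ccrd_runs):
    return ccrd_runs["activity_exp"].to_numpy(float)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
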