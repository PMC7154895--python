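import pytest

from loliumsim.demography import PopulationParams
from loliumsim.emergence import CohortSchedule, EmergenceModel
from loliumsim.management import ControlRates, strategy_library
from loliumsim.stochastics import mean_params


@pytest.fixture(scope="session")
def susceptible():
    return PopulationParams.susceptible()


@pytest.fixture(scope="session")
def resistant():
    return PopulationParams.resistant()


@pytest.fixture(scope="session")
def control():
    return ControlRates()


@pytest.fixture(scope="session")
def susceptible_means(susceptible, control):
    return mean_params(susceptible, control)


@pytest.fixture(scope="session")
def resistant_means(resistant, control):
    return mean_params(resistant, control)


@pytest.fixture(scope="session")
def model():
    return EmergenceModel()


@pytest.fixture(scope="session")
def schedule():
    return CohortSchedule()


@pytest.fixture(scope="session")
def strategies():
    return strategy_library()
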