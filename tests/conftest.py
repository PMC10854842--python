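import pytest

from alkanediet import (
    AlkaneID,
    DietCompositionModel,
    SimConfig,
    default_fixtures,
    reference_profiles,
    simulate_flock,
)

C25, C27, C29, C31, C33 = (AlkaneID(n) for n in (25, 27, 29, 31, 33))


@pytest.fixture(scope="session")
def components():
    """Reference feed + alfalfa alkane profiles (mg/kg DM)."""
    return default_fixtures()[0]


@pytest.fixture(scope="session")
def recovery_table():
    """Reference diet-specific mean recoveries."""
    return default_fixtures()[1]


@pytest.fixture(scope="session")
def profiles():
    return reference_profiles()


@pytest.fixture(scope="session")
def noiseless_flock():
    """48 hens, assay noise off: the estimator should invert exactly."""
    return simulate_flock(SimConfig(noise_cv=0.0, seed=11))


@pytest.fixture(scope="session")
def noisy_flock():
    """48 hens at the default study conditions (5% assay CV)."""
    return simulate_flock(SimConfig(seed=11))


@pytest.fixture(scope="session")
def fitted_noisy(noisy_flock, components, recovery_table):
    animals, _ = noisy_flock
    return DietCompositionModel(animals, components, recovery_table).fit()
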