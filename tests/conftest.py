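import numpy as np
import pytest

from enf.foodb import CompositionEntry, FoodGroupRegistry, FoodItemCoefficient
from enf.intake import GroupProfile
from enf.synthetic_data import GeneratorConfig, generate


@pytest.fixture(scope="session")
def registry():
    return FoodGroupRegistry.from_ids(["g1", "g2", "g3"])


@pytest.fixture(scope="session")
def coefficient_rows():
    return [
        FoodItemCoefficient("beef", "g1", "boiled", 30000.0, 15000.0, 200.0),
        FoodItemCoefficient("beef", "g1", "fried", 32000.0, 15500.0, 210.0),
        FoodItemCoefficient("beans", "g2", "boiled", 1200.0, 800.0, 4.0),
        FoodItemCoefficient("coffee", "g3", "raw", 400.0, 900.0, 2.0),
    ]


@pytest.fixture(scope="session")
def composition_entries():
    return [
        CompositionEntry("beef", "g1", 250.0),
        CompositionEntry("beef_dry", "g1", 150.0),
        CompositionEntry("beans", "g2", 90.0),
        CompositionEntry("coffee", "g3", 10.0),
    ]


@pytest.fixture
def simple_profiles():
    return {
        "g1": GroupProfile("g1", 120.0, 30000.0, 15000.0, 200.0, 250.0),
        "g2": GroupProfile("g2", 80.0, 1200.0, 800.0, 4.0, 90.0),
        "g3": GroupProfile("g3", 200.0, 400.0, 900.0, 2.0, 10.0),
    }


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-person, 12-group synthetic cohort used across integration tests."""
    return generate(GeneratorConfig(n_respondents=60, n_groups=12, seed=42))


def random_small_cohort(seed: int, n: int = 12, groups: int = 8):
    return generate(GeneratorConfig(n_respondents=n, n_groups=groups,
                                    seed=seed))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
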