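import numpy as np
import pytest

from responsekit.dose_response import build_response_matrix
from responsekit.feature_prep import dichotomize
from responsekit.synthetic_data import (
    PlantedCompound,
    SimulationDesign,
    simulate_panel,
    simulate_plates,
)


@pytest.fixture(scope="session")
def planted_panel():
    """48-line panel with a feature-driven, a subtype-driven and a null drug."""
    design = SimulationDesign(
        n_lines=48,
        seed=7,
        compounds=[
            PlantedCompound("featdrug", driver="feature", n_planted=15,
                            effect_size=2.0),
            PlantedCompound("subdrug", driver="subtype"),
            PlantedCompound("nulldrug", driver="null"),
        ],
    )
    return simulate_panel(design)


@pytest.fixture(scope="session")
def planted_response_matrix(planted_panel):
    plates = simulate_plates(planted_panel.true_gi50, planted_panel.design)
    return build_response_matrix(plates)


@pytest.fixture(scope="session")
def featdrug_labels(planted_response_matrix):
    return dichotomize(planted_response_matrix, "featdrug")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
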