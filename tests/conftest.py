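import numpy as np
import pytest

from tspopet import FrameSchedule, build_phantom, simulate_1tc
from tspopet.cohort import StudyConfig, train_class_database
from tspopet.simulate import DEFAULT_INPUT, CohortConfig


@pytest.fixture(scope="session")
def schedule():
    return FrameSchedule.default()


@pytest.fixture(scope="session")
def reference_tac(schedule):
    """Noiseless one-tissue reference TAC at the default kinetics."""
    return simulate_1tc(DEFAULT_INPUT, 0.12, 0.25, schedule)


@pytest.fixture(scope="session")
def noiseless_phantom():
    return build_phantom(noise_alpha=0.0, seed=1)


@pytest.fixture(scope="session")
def noisy_phantom():
    return build_phantom(noise_alpha=0.5, seed=7)


@pytest.fixture(scope="session")
def class_db():
    """Class database trained on a six-animal stroke-like cohort run
    through the segmentation/labelling pipeline."""
    return train_class_database(StudyConfig(), CohortConfig(), seed=42)
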