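import numpy as np
import pytest

from connclass import Cohort, SimulationConfig, generate_cohort
from connclass.connectome import CONTROL, PATIENT, devectorize


def cohort_from_features(X: np.ndarray, y: np.ndarray, n_regions: int) -> Cohort:
    """Wrap a feature matrix (rows = subjects) into a Cohort."""
    mats = [devectorize(row, n_regions) for row in X]
    labels = np.where(np.asarray(y) == 1, PATIENT, CONTROL).astype(object)
    return Cohort(mats, labels, threshold=0.0)


@pytest.fixture(scope="session")
def small_signal_cohort():
    """12-region, 8+8-subject cohort with 5 strongly raised edges."""
    config = SimulationConfig(
        n_regions=12, n_patients=8, n_controls=8, density=0.5,
        affected_edges=5, effect_multiplier=6.0, seed=42,
    )
    synth = generate_cohort(config)
    return synth


@pytest.fixture(scope="session")
def default_cohort():
    """Default-condition cohort: 90 regions, 22 patients + 26 controls."""
    return generate_cohort(SimulationConfig(seed=7))
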