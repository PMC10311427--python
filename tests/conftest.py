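import warnings

import pytest

from ropscreen.evaluate import PipelineConfig, fit_pipeline
from ropscreen.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """~1500 infants with the default study-condition generator."""
    records, truth = generate_cohort(SimulationConfig(n_infants=1500, seed=42))
    return records, truth


@pytest.fixture(scope="session")
def big_cohort():
    """20k infants for marginal-distribution checks (shared across tests)."""
    records, truth = generate_cohort(SimulationConfig(n_infants=20_000,
                                                      seed=99))
    return records, truth


@pytest.fixture(scope="session")
def fitted_pipeline(small_cohort):
    """Full pipeline (prescreen + screen + cutoffs) fitted on small_cohort."""
    records, _ = small_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pipe = fit_pipeline(records,
                            PipelineConfig(select_interactions=False, seed=42))
    return pipe
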