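import numpy as np
import pandas as pd
import pytest

from lncpair.pipeline import PipelineConfig, run_pipeline_on_cohort
from lncpair.simulate import SimulationParams, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One strong-signal cohort at the study conditions (seed 1)."""
    return generate_cohort(SimulationParams(seed=1))


@pytest.fixture(scope="session")
def default_result(default_cohort):
    """Full pipeline run on the strong-signal cohort."""
    return run_pipeline_on_cohort(default_cohort, PipelineConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort for plumbing tests."""
    params = SimulationParams(n_tumor=120, n_normal=30, n_lnc=60,
                              n_irgene=40, n_linked=20, n_de=10, seed=7)
    return generate_cohort(params)


@pytest.fixture()
def toy_survival():
    """Six-subject survival table with hand-checkable statistics."""
    return pd.DataFrame({
        "os_time": [1.0, 2.0, 4.0, 3.0, 5.0, 6.0],
        "os_event": [1, 1, 0, 1, 1, 0],
    }, index=[f"S{i}" for i in range(1, 7)])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
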