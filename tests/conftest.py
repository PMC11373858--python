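import numpy as np
import pytest

from mgm_growth import (
    DEFAULT_FEMALE,
    DEFAULT_MALE,
    ObservationModel,
    generate_dataset,
    process_table,
    run_pipeline,
)


@pytest.fixture(scope="session")
def male_params():
    return DEFAULT_MALE


@pytest.fixture(scope="session")
def female_params():
    return DEFAULT_FEMALE


@pytest.fixture(scope="session")
def clean_dataset():
    """Small deterministic experiment: no weighing noise, no random effects."""
    obs = ObservationModel(weighing_cv=0.0)
    re0 = {"alpha": 0.0, "gamma": 0.0, "W_mat": 0.0, "W_0": 0.0}
    raw, meta = generate_dataset(
        seed=11, obs_model=obs, re_spec=re0, attrition=0, n_male=3, n_female=3
    )
    return raw, meta


@pytest.fixture(scope="session")
def clean_series(clean_dataset):
    raw, meta = clean_dataset
    return process_table(raw, m=0.15, E_f=17.0, window=3)


@pytest.fixture(scope="session")
def clean_pipeline(clean_dataset):
    """Pipeline result on the clean dataset, shared across evaluation tests."""
    raw, meta = clean_dataset
    return run_pipeline(raw, seed=11, truth=meta, per_individual=True)
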