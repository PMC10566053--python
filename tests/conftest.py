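import numpy as np
import pandas as pd
import pytest

from uromet import (
    CohortConfig,
    PipelineConfig,
    PreprocessConfig,
    SelectionConfig,
    generate_cohort,
    preprocess_pipeline,
)

TRUE_MARKERS = tuple(f"M{j:04d}" for j in range(1, 11))


def small_cohort_config(seed=0, n_informative=8, n_features=150):
    """A fast, structurally faithful cohort for integration tests:
    strong planted markers so the study's AUC ordering holds at n=150."""
    return CohortConfig(
        n_per_group_training={"benign": 30, "VLR/LR": 10, "FIR": 10, "UIR": 15, "HR/VHR": 25, "mPC": 10},
        n_per_group_validation={"benign": 24, "VLR/LR": 4, "FIR": 4, "UIR": 6, "HR/VHR": 8, "mPC": 4},
        n_features=n_features,
        n_informative=n_informative,
        informative_effect=1.8,
        detected_fraction=0.4,
        seed=seed,
    )


@pytest.fixture(scope="session")
def tiny_tables():
    return generate_cohort(CohortConfig.tiny(seed=42))


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort (Table-1 strata counts, 1,941 features)."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def small_tables():
    return generate_cohort(small_cohort_config(seed=3))


@pytest.fixture(scope="session")
def small_normalized(small_tables):
    subjects, peaks = small_tables
    return subjects, preprocess_pipeline(peaks, subjects, PreprocessConfig())


def fast_pipeline_config(seed=0, **kw):
    return PipelineConfig(
        synthetic=small_cohort_config(),
        selection=SelectionConfig(rounds=2, k_folds=3, top_n_recurring=12),
        seed=seed,
        **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
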