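import numpy as np
import pandas as pd
import pytest

import splitstat as ss


@pytest.fixture(scope="session")
def study1_table() -> pd.DataFrame:
    """Study-1-scale synthetic table (health literacy / nutrition knowledge)."""
    return ss.generate_study1(612, seed=11)


@pytest.fixture(scope="session")
def study2_table() -> pd.DataFrame:
    """Study-2-scale synthetic table (cognitive restraint / BMI)."""
    return ss.generate_study2(586, seed=11)


@pytest.fixture(scope="session")
def study2_fit(study2_table):
    """Centered moderated regression of F/V intake on restraint x BMI."""
    return ss.ModeratedOLS(
        study2_table,
        "fv_intake",
        ["cognitive_restraint", "bmi", "cognitive_restraint:bmi"],
        center=True,
    ).fit()


@pytest.fixture(scope="session")
def study1_fit(study1_table):
    """Quadratic regression of label accuracy (uncentered scales)."""
    return ss.ModeratedOLS(
        study1_table,
        "label_accuracy",
        ["nutrition_knowledge", "health_literacy", "health_literacy^2"],
    ).fit()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
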