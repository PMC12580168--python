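import numpy as np
import pandas as pd
import pytest

from pvpassport import generate_cohort, study_cohort_config, train_pv_model
from pvpassport.pvmodel import train_default_model


@pytest.fixture(scope="session")
def default_model():
    """The package's default boosted-tree PV estimator (deterministic)."""
    return train_default_model(seed=0)


@pytest.fixture(scope="session")
def clean_cohort():
    """A clean 40-subject monitoring cohort with ground truth."""
    return generate_cohort(study_cohort_config(seed=11))


def make_linear_frame(n=60, slope=5.0, intercept=2000.0, seed=0):
    """Noise-free samples whose measured PV is an exact linear function
    of [Hb] (slope per g·dL⁻¹); all other features are uninformative."""
    rng = np.random.default_rng(seed)
    hb = rng.uniform(12.0, 17.0, size=n)
    frame = pd.DataFrame(
        {
            "subject_id": [f"X{i}" for i in range(n)],
            "sex": ["male"] * n,
            "age": rng.uniform(20, 35, size=n),
            "height": rng.uniform(165, 195, size=n),
            "weight": np.full(n, 75.0),
            "visit_index": np.ones(n, dtype=int),
            "hb": hb,
            "hct": rng.uniform(38, 48, size=n),
            "rbc": rng.uniform(4.0, 5.5, size=n),
            "ret_pct": rng.uniform(0.4, 1.8, size=n),
            "mcv": rng.uniform(82, 95, size=n),
            "mchc": rng.uniform(32, 35, size=n),
            "pv_measured": slope * hb + intercept,
        }
    )
    return frame


@pytest.fixture()
def linear_frame():
    return make_linear_frame()


@pytest.fixture()
def linear_model(linear_frame):
    return train_pv_model(linear_frame, regressor_kind="linear", seed=0)
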