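import numpy as np
import pandas as pd
import pytest

from rsindex.datamodel import WardObservationSet
from rsindex.synthetic import SyntheticCohortConfig, generate_cohort


def make_obs(admission_id="a1", obs_time=0, heart_rate=70.0,
             systolic_bp=120.0, resp_rate=16.0, temperature=37.0,
             spo2=98.0, supplemental_o2=False, avpu="A", **overrides):
    """An observation set with every vital in its normal range."""
    values = dict(admission_id=admission_id, obs_time=obs_time,
                  heart_rate=heart_rate, systolic_bp=systolic_bp,
                  resp_rate=resp_rate, temperature=temperature, spo2=spo2,
                  supplemental_o2=supplemental_o2, avpu=avpu)
    values.update(overrides)
    return WardObservationSet(**values)


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-admission synthetic cohort shared across tests."""
    cohort, truth = generate_cohort(
        SyntheticCohortConfig(n_admissions=300, seed=11))
    return cohort, truth


@pytest.fixture(scope="session")
def normal_cloud():
    """A Gaussian vital-sign cloud in realistic ward units."""
    rng = np.random.default_rng(42)
    X = rng.normal(size=(400, 5)) * [9.0, 11.0, 2.2, 0.35, 1.3] \
        + [78.0, 121.0, 16.0, 36.9, 96.5]
    X[:, 4] = np.minimum(X[:, 4], 100.0)
    return pd.DataFrame(
        X, columns=["heart_rate", "systolic_bp", "resp_rate",
                    "temperature", "spo2"])
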