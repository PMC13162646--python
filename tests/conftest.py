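import warnings

import numpy as np
import pandas as pd
import pytest

from trapcomm.synth import SurveyScenario, generate_survey


@pytest.fixture(scope="session")
def small_scenario():
    return SurveyScenario(
        n_sites=40, n_species=8, survey_days=140, disturbance_rate=3.0, seed=11
    )


@pytest.fixture(scope="session")
def small_survey(small_scenario):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_survey(small_scenario)


def make_records(rows):
    """Records frame from (camera, species, minutes-from-epoch) triples."""
    t0 = pd.Timestamp("2020-01-01")
    return pd.DataFrame(
        {
            "camera_id": [r[0] for r in rows],
            "species": [r[1] for r in rows],
            "timestamp": [t0 + pd.Timedelta(minutes=r[2]) for r in rows],
        }
    )


def make_deployments(cameras, days=30, camera_type="A"):
    t0 = pd.Timestamp("2020-01-01")
    return pd.DataFrame(
        [
            {
                "camera_id": c,
                "start": t0,
                "end": t0 + pd.Timedelta(days=days, hours=-1),
                "camera_type": camera_type,
            }
            for c in cameras
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
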