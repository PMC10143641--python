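import numpy as np
import pandas as pd
import pytest

from relkin import make_design_series, reference, simulate_release_study
from relkin.profiles import profiles_from_frame

TRUTH = (reference.A_INTERCEPT, reference.M_EXPONENT, reference.N_MEAN)


@pytest.fixture(scope="session")
def design_series():
    return make_design_series()

@pytest.fixture(scope="session")
def designs_by_id(design_series):
    return {d.design_id: d for d in design_series}


@pytest.fixture(scope="session")
def noiseless_study(design_series):
    """Zero-noise simulated study over all ten designs (3 replicates)."""
    rng = np.random.default_rng(0)
    frames = [simulate_release_study(design=d, truth=TRUTH, seed=rng)
              for d in design_series]
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def noiseless_profiles(noiseless_study):
    return profiles_from_frame(noiseless_study)
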