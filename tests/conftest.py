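import numpy as np
import pytest

from glomcode import population_analysis as pa
from glomcode import scenes
from glomcode import synthetic_population as sp


@pytest.fixture(scope="session")
def pink_image():
    return scenes.generate_pink_image(96, 512, slope=-2.0, seed=1)


@pytest.fixture(scope="session")
def tuning():
    return sp.generate_tuning(seed=0)


@pytest.fixture(scope="session")
def trial_data(tuning):
    return sp.generate_trials(tuning, seed=0)


@pytest.fixture(scope="session")
def amplitudes(trial_data):
    tensor, _ = trial_data
    return pa.peak_amplitudes(tensor)


@pytest.fixture(scope="session")
def walking_session():
    return sp.generate_walking(duration_s=300.0, seed=0)


def spearman(x, y):
    from scipy import stats

    return stats.spearmanr(x, y).statistic
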