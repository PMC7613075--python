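import numpy as np
import pytest

from swaplab import taskgen


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def exp1_trials_location_report():
    """500 Exp-1-style arrays (set size 6, 30 deg separations), one level."""
    cfg = taskgen.exp1_config("location-report", n_trials_per_level=1, seed=77)
    gen = np.random.default_rng(77)
    return [taskgen.generate_array(cfg, gen, level="low") for _ in range(500)]


@pytest.fixture(scope="session")
def mixture_records(exp1_trials_location_report):
    """Responses from a known three-component process on the session trials."""
    params = taskgen.MixtureGenParams(0.6, 0.3, 0.1, kappa=8.0)
    return taskgen.simulate_responses(exp1_trials_location_report, "mixture",
                                      params, np.random.default_rng(7))
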