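import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240820)


@pytest.fixture(scope="session")
def quiet_stream():
    """A 2-h all-normal synthetic stream with modest variability."""
    from holterchaos import SimConfig, generate_beat_times

    cfg = SimConfig(duration_h=2.0, hr_mesor=95.0, hr_circ_amplitude=0.0,
                    lf_depth=0.03, hf_depth=0.03, fractal_alpha=0.8,
                    fractal_sd=4.0, seed=11)
    return generate_beat_times(cfg)
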