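import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ca_transient():
    from zoomfit import gen_ca_transient

    return gen_ca_transient()


@pytest.fixture(scope="session")
def toy_target(ca_transient):
    from zoomfit import make_reference_target

    return make_reference_target(ca=ca_transient)


@pytest.fixture(scope="session")
def toy_batch(toy_target):
    """A small simulated batch over the toy parameter space (shared, read-only)."""
    import zoomfit as zf
    from zoomfit.batch import SimulationBatch
    from zoomfit.pipeline import simulate_design_metrics

    space = zf.toy_parameter_space()
    params = zf.lhd_sample(space, 80, seed=1234).to_frame()
    metrics, errors, scalers = simulate_design_metrics(
        params, zf.toy_simulator(), toy_target, (0.9, 1.0, 1.1)
    )
    return SimulationBatch(params, metrics, errors)
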