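import numpy as np
import pytest

import adcostsim as ad


@pytest.fixture(scope="session")
def baseline():
    return ad.build_baseline_model()


@pytest.fixture(scope="session")
def eu_projection():
    return ad.generate_projection(ad.eu_preset())


@pytest.fixture(scope="session")
def eu_calibration(eu_projection):
    return ad.calibrate(eu_projection)


@pytest.fixture(scope="session")
def toy_projection():
    return ad.toy_projection(1e5)


@pytest.fixture(scope="session")
def toy_calibration(toy_projection):
    return ad.calibrate(toy_projection)


@pytest.fixture(scope="session")
def full_run(eu_projection):
    """One shared end-to-end run of every scenario on the EU-like preset."""
    return ad.run_all(ad.RunConfig())


def assert_row_stochastic(model, tol=1e-12):
    rows = model.q.sum(axis=1) + model.death
    assert np.abs(rows - 1.0).max() <= tol
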