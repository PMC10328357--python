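import numpy as np
import pytest

import charterm as ct

SUITE_SEED = 1


@pytest.fixture(scope="session")
def olea_calibration():
    """Default low-noise synthetic calibration for the olive preset."""
    cfg = ct.taxon_preset("Olea")
    return cfg, ct.simulate_calibration(cfg, seed=SUITE_SEED)


@pytest.fixture(scope="session")
def olea_model(olea_calibration):
    cfg, cal = olea_calibration
    est = ct.TemperaturePLS().fit(cal.matrix, cal.temperatures)
    return cfg, cal, est


@pytest.fixture()
def rng():
    return np.random.default_rng(SUITE_SEED)
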