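import numpy as np
import pytest

import pcmodel as pm


@pytest.fixture(scope="session")
def toy_model():
    return pm.make_toy_yeast()


@pytest.fixture(scope="session")
def toy_pc(toy_model):
    return pm.build_pc_model(toy_model)


@pytest.fixture(scope="session")
def batch_solution(toy_pc):
    """Growth-maximised solution at full transporter saturation."""
    return pm.maximize_growth(toy_pc)


@pytest.fixture(scope="session")
def fine_sweep(toy_pc):
    """Fine transporter-saturation sweep shared across tests."""
    return pm.saturation_sweep(toy_pc, list(np.linspace(0.05, 1.0, 30)))


@pytest.fixture(scope="session")
def regime_boundaries(toy_pc):
    return pm.locate_regime_boundaries(toy_pc, s_lo=0.02, s_tol=5e-4)


@pytest.fixture(scope="session")
def galactose_run(toy_pc):
    return pm.condition_run(toy_pc, pm.OVERLAYS["galactose"])
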