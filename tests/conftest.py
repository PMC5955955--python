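import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def iv_protocols():
    from etmodel.protocols import build_iv_protocol

    return build_iv_protocol()


@pytest.fixture(scope="session")
def genotype_params():
    from etmodel.config import load_default_genotypes

    return load_default_genotypes()


@pytest.fixture(scope="session")
def act_gate():
    from etmodel.gating import GateParams

    return GateParams(Vh=-30.0, k=10.0, Amp=5.0, Vmax=-50.0, sigma=20.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
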