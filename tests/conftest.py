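import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def constants():
    from anophys.buffering import load_constants

    return load_constants()


@pytest.fixture(scope="session")
def hedta_recipe():
    from anophys.buffering import SolutionSpec

    # standard intracellular solution: 130 CsCl, 10 HEPES, 10 HEDTA, pH 7.2
    return SolutionSpec(salts={"CsCl": 130, "HEPES": 10},
                        ligands_mM={"HEDTA": 10}, pH=7.2, temperature_c=22.0)


@pytest.fixture(scope="session")
def standard_protocol():
    from anophys.pipeline import standard_protocol

    return standard_protocol()


@pytest.fixture(scope="session")
def quiet_gating():
    """WT gating with noise, leak and capacitative transients removed."""
    from dataclasses import replace

    from anophys.simulate import get_gating

    return replace(get_gating("WT-HEK"), noise_sd_pA=0.0, leak_ns=0.0,
                   cap_amp_pA=0.0)


@pytest.fixture(scope="session")
def nonselective():
    from anophys.simulate import get_permeation

    return get_permeation("nonselective")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
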