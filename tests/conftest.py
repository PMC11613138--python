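import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from meltfold import oligo, presets, synth


@pytest.fixture(scope="session")
def sreseg16():
    return oligo.build_sre_segment(16)


@pytest.fixture(scope="session")
def default_cfg():
    return synth.SynthConfig(seed=11)


@pytest.fixture(scope="session")
def uv_series(default_cfg):
    return synth.synth_uv_series(default_cfg)


@pytest.fixture(scope="session")
def shift_profiles(default_cfg):
    return synth.synth_shift_profiles(default_cfg)
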