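import numpy as np
import pytest

from etphase.synthetic import SyntheticSpec, generate_session

FS = 250.0


@pytest.fixture(scope="session")
def ec_session():
    """One eyes-closed 120 s session at 10 dB, shared across tests."""
    spec = SyntheticSpec(duration_s=120.0, state="EC", target_snr_db=10.0, seed=5)
    rec, events, phase = generate_session(spec)
    return spec, rec, events, phase


@pytest.fixture(scope="session")
def task_session():
    """One 300 s task session with trial / intertrial structure."""
    spec = SyntheticSpec(duration_s=300.0, state="task", target_snr_db=6.0, seed=9)
    rec, events, phase = generate_session(spec)
    return spec, rec, events, phase


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
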