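import numpy as np
import pytest

import adaptecg as a


@pytest.fixture(scope="session")
def gmrf():
    return a.default_gmrf()


@pytest.fixture(scope="session")
def policy():
    return a.SamplingPolicy(fs=500.0, fm=100.0, quant_bits=6)


@pytest.fixture(scope="session")
def record():
    """Default 12-lead, 60 bpm, 10 s record with ground-truth borders."""
    return a.generate_ecg(a.SynthConfig(seed=7))


@pytest.fixture(scope="session")
def clean_record():
    """Low-noise record for delineation-accuracy checks."""
    return a.generate_ecg(a.SynthConfig(seed=11, noise_rms_uv=2.0))


@pytest.fixture(scope="session")
def encoded(record, gmrf, policy):
    ecg, annotations = record
    nu = a.encode(ecg, gmrf, policy, annotations=annotations)
    return ecg, annotations, nu, a.decode(nu)
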