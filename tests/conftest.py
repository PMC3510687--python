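import numpy as np
import pytest

from stimvarx import (
    StimulusTrain,
    random_stable_mvarx,
    simulate_session,
)
from stimvarx.preprocessing import segment_epochs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_session(
    d=4,
    p=3,
    ell=5,
    radius=0.8,
    n_pulses=30,
    isi=100,
    seed=0,
    input_gain=1.0,
    noise_scale=1.0,
):
    """Standard synthetic stimulation session used across tests."""
    model = random_stable_mvarx(
        d, p, ell, spectral_radius_target=radius, seed=seed,
        input_gain=input_gain, noise_scale=noise_scale,
    )
    train = StimulusTrain.regular(n_pulses=n_pulses, isi=isi, start=isi)
    n = int(train.pulse_times[-1] + 2 * isi)
    session = simulate_session(model, train, n_samples=n, seed=seed + 1)
    return model, train, session


def session_epochs(session, train, pre=12, length=100):
    return segment_epochs(
        session.y, session.x, train.pulse_times, pre=pre, length=length,
        fs=session.fs, channel_names=session.channel_names,
    )


@pytest.fixture
def small_session():
    return make_session(d=4, p=3, ell=5, seed=42)
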