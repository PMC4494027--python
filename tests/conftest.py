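import numpy as np
import pytest

from blockmvpa.design import DesignParams, build_session_timeline
from blockmvpa.glm import ZMap
from blockmvpa.simulate import (
    AwarenessModel,
    NoiseSpec,
    SignalSpec,
    simulate_awareness,
    simulate_bold,
)


@pytest.fixture
def default_params():
    return DesignParams()


@pytest.fixture
def default_events(default_params):
    return build_session_timeline(default_params, seed=42)


@pytest.fixture
def small_params():
    # 3 blocks/condition: 10 + 6 * 17.5 = 115 s, 46 volumes
    return DesignParams(blocks_per_cond=3)


@pytest.fixture
def tiny_shape():
    return (4, 4, 3)


@pytest.fixture
def quiet_noise():
    return NoiseSpec(white_sd=0.0, ar1=0.0, drift_amplitude=0.0, seed=0)


@pytest.fixture
def flat_zmap():
    return ZMap(np.zeros((4, 4, 3)))


def make_run(events, shape, params, amp_a=None, amp_b=None, offsets=None,
             noise=None, seed=0):
    """Convenience builder used across test modules."""
    cond_a, cond_b = params.conditions
    amplitudes = {}
    if amp_a is not None:
        amplitudes[cond_a] = amp_a
    if amp_b is not None:
        amplitudes[cond_b] = amp_b
    signal = SignalSpec(
        baseline=100.0, amplitudes=amplitudes, offsets=offsets or {}
    )
    if noise is None:
        noise = NoiseSpec(white_sd=0.0, ar1=0.0, drift_amplitude=0.0, seed=seed)
    return simulate_bold(
        events, signal, noise, shape, tr_s=params.tr_s,
        n_volumes=params.n_volumes,
    )


@pytest.fixture
def labeled_events(default_events):
    model = AwarenessModel(seed=7)
    return simulate_awareness(default_events, model)
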