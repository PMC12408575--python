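import numpy as np
import pytest

from dopplerauth import (
    SimulationConfig,
    make_subject_profile,
    make_subject_profiles,
    simulate_recording,
)


@pytest.fixture(scope="session")
def profiles():
    return make_subject_profiles(3, seed=11)


@pytest.fixture(scope="session")
def clean_recording(profiles):
    """A recording with the beat train and respiration only (no noise,
    power line, or motion bursts)."""
    cfg = SimulationConfig(
        duration=30.0, noise_sd=0.0, powerline_amp=0.0, motion_burst_rate=0.0, seed=42
    )
    return simulate_recording(profiles[0], cfg)


@pytest.fixture(scope="session")
def noisy_recording(profiles):
    return simulate_recording(profiles[0], SimulationConfig(duration=30.0, seed=7))


def finite_diff_input_grad(mod, x, g, eps=1e-6):
    """Numerical dL/dx for L = sum(forward(x) * g)."""
    num = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp = x.copy()
        xp[i] += eps
        xm = x.copy()
        xm[i] -= eps
        num[i] = (np.sum(mod.forward(xp) * g) - np.sum(mod.forward(xm) * g)) / (2 * eps)
    return num


def finite_diff_param_grads(mod, x, g, eps=1e-6):
    """Numerical dL/dp for each parameter tensor of ``mod``."""
    grads = []
    for p in mod.parameters():
        num = np.zeros_like(p.value)
        it = np.nditer(p.value, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            old = p.value[i]
            p.value[i] = old + eps
            yp = np.sum(mod.forward(x) * g)
            p.value[i] = old - eps
            ym = np.sum(mod.forward(x) * g)
            p.value[i] = old
            num[i] = (yp - ym) / (2 * eps)
        grads.append(num)
    return grads
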