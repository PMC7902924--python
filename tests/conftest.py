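import numpy as np
import pytest

from ils_rl import ils_env, rl_agents


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def high_config():
    return ils_env.builtin_config("high")


@pytest.fixture
def low_config():
    return ils_env.builtin_config("low")


@pytest.fixture
def medium_config():
    return ils_env.builtin_config("medium")


@pytest.fixture
def pvl2_high_params():
    """Published high-condition PVL-2 parameter set."""
    return rl_agents.params_from_dict("pvl2", {
        "shape_alpha": 0.851, "loss_aversion_lambda": 4.797,
        "consistency_c": 0.789, "recency_A": 0.099})


class ScriptedRNG:
    """Stand-in RNG returning a scripted sequence of uniform draws."""

    def __init__(self, values):
        self.values = list(values)
        self.i = 0

    def uniform(self, low=0.0, high=1.0, size=None):
        if size is not None:
            n = int(np.prod(size))
            out = np.array([self.uniform(low, high) for _ in range(n)])
            return out.reshape(size)
        v = self.values[self.i]
        self.i += 1
        return low + (high - low) * v


@pytest.fixture
def scripted_rng_factory():
    return ScriptedRNG
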