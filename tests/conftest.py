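import numpy as np
import pytest

from mclswt import ModelConfig, SWTModel, SimConfig, build_mirror_map, simulate_dataset


@pytest.fixture(scope="session")
def mirror_map_c3c4():
    return build_mirror_map(["C3", "Cz", "C4"])


@pytest.fixture(scope="session")
def tiny_model_cfg():
    """A small configuration for fast model tests (short trials)."""
    return ModelConfig(
        temporal_kernel=5, d_model=8, n_heads=2, window_size=4,
        pool_kernel=8, pool_stride=4, mlp_hidden=16, dtype="float64",
    )


@pytest.fixture(scope="session")
def tiny_trials():
    """A small simulated dataset: 2 subjects x 8 short trials at 125 Hz."""
    # 120 samples -> L' = 116 with kernel 5, divisible by window 4
    cfg = SimConfig(fs=125.0, trial_duration=0.96, cue_onset=0.2, seed=11)
    return simulate_dataset(2, 8, cfg, seed=11)


def finite_diff_grad(f, x, eps=1e-6):
    """Central finite differences of a scalar function of an array."""
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        xp = x.copy()
        xp[idx] += eps
        xm = x.copy()
        xm[idx] -= eps
        g[idx] = (f(xp) - f(xm)) / (2 * eps)
        it.iternext()
    return g
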