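import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mmgbsa_ie as m
from mmgbsa_ie.entropy import Window, WindowPlan

settings.register_profile(
    "fast", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("fast")


@pytest.fixture(scope="session")
def toy():
    """3-residue (ALA/SER/GLU) complex with a 60-frame jittered trajectory."""
    spec = m.ToySpec(n_pocket_residues=3, n_frames=60, jitter=0.03)
    return m.make_toy_complex(spec, seed=2)


@pytest.fixture(scope="session")
def small_windows():
    """Two 30-frame windows covering the 60-frame toy trajectory."""
    plan = WindowPlan(window_length_ps=30.0, n_windows_per_replicate=2,
                      n_replicates=1, enthalpy_frames_per_window=10)
    return [Window(0, 0, 30), Window(0, 30, 60)], plan


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
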