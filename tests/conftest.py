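import numpy as np
import pytest

import gradmap as gm


@pytest.fixture(scope="session")
def small_scene():
    """One-blob scene with a single linear planted gradient."""
    return gm.build_scene((14, 12, 10), n_roi_blobs=1, gradient_degrees=(1,),
                          n_networks=8, snr=5.0, seed=7)


@pytest.fixture(scope="session")
def two_gradient_scene():
    """One-blob scene with orthogonal linear + quadratic gradients."""
    return gm.build_scene((20, 16, 12), n_roi_blobs=1, gradient_degrees=(1, 2),
                          n_networks=12, snr=5.0, seed=3)


@pytest.fixture(scope="session")
def small_bold(small_scene):
    bold, brain = gm.synthesize_bold(small_scene, t=120, seed=21)
    return bold, brain


@pytest.fixture
def rng():
    return np.random.default_rng(0)
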