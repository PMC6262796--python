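import numpy as np
import pytest

from gutcount.core import ImageStack
from gutcount.synthetic import SimulationParams, place_nuclei, render_channels


@pytest.fixture
def small_params():
    """Fast, clean regime: small domain, no blur, no noise."""
    return SimulationParams(
        shape_zyx=(20, 64, 64),
        n_small=5,
        n_big=3,
        clone_fraction=0.5,
        seed=7,
    )


@pytest.fixture
def small_truth(small_params):
    return place_nuclei(small_params)


@pytest.fixture
def small_stack(small_truth, small_params):
    return render_channels(small_truth, small_params)


@pytest.fixture
def make_simulation():
    """Factory: place + render with overrides on the fast default regime."""

    def _make(seed=0, **overrides):
        fields = dict(
            shape_zyx=(20, 64, 64),
            n_small=5,
            n_big=3,
            clone_fraction=0.5,
            seed=seed,
        )
        fields.update(overrides)
        params = SimulationParams(**fields)
        truth = place_nuclei(params)
        return params, truth, render_channels(truth, params)

    return _make


@pytest.fixture
def flat_stack():
    """Minimal hand-built two-channel stack for unit tests."""
    vox = np.zeros((2, 4, 8, 8))
    vox[0, 1:3, 2:6, 2:6] = 100.0
    vox[1, 1:3, 2:6, 2:6] = 50.0
    return ImageStack(vox, voxel_size_zyx=(1.0, 0.5, 0.5), channel_names=["dna", "gfp"])
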