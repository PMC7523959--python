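import numpy as np
import pytest

from fpfseg.core import ImagePair, InstanceSet
from fpfseg.data import micro_scene_config, simulate_scene


@pytest.fixture(scope="session")
def micro_scene():
    """One clustered 128x128 scene with moderate noise."""
    return simulate_scene(micro_scene_config(seed=11))


@pytest.fixture(scope="session")
def clean_scene():
    """Noiseless, isolated-cell scene for threshold-based oracles."""
    return simulate_scene(micro_scene_config(
        seed=5, cluster_fraction=0.0, noise_sd=0.0, contact_attenuation=0.0))


def masks_to_set(shape, masks, scores=None):
    return InstanceSet(shape=shape, masks=[np.asarray(m, dtype=bool) for m in masks],
                       scores=None if scores is None else np.asarray(scores, float))


@pytest.fixture
def toy_set():
    return masks_to_set
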