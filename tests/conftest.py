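import numpy as np
import pytest

from contrastshift import phantom
from contrastshift.grids import HU, LabelVolume, VolumeGrid


@pytest.fixture(scope="session")
def small_config():
    """Desk phantom at 32^3 with default organs and 10 HU noise."""
    return phantom.default_config(grid=32, noise_sd_hu=10.0, seed=0)


@pytest.fixture(scope="session")
def noisefree_config():
    import dataclasses

    cfg = phantom.default_config(grid=32, noise_sd_hu=0.0, seed=0)
    organs = [dataclasses.replace(o, texture_amplitude_hu=0.0) for o in cfg.organs]
    return dataclasses.replace(cfg, organs=organs)


@pytest.fixture(scope="session")
def noisy_case(small_config):
    return phantom.make_phantom(small_config, case_seed=3)


@pytest.fixture(scope="session")
def noisefree_case(noisefree_config):
    return phantom.make_phantom(noisefree_config, case_seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def ellipsoid_pair():
    """Aligned smooth image + centered ellipsoid mask on a 24^3 grid."""
    n = 24
    coords = np.stack(np.meshgrid(*[np.arange(n)] * 3, indexing="ij"), axis=-1)
    center = (n - 1) / 2
    rel = (coords - center) / np.array([8.0, 6.0, 5.0])
    mask = (np.sum(rel**2, axis=-1) <= 1.0).astype(np.uint8)
    img = 40.0 + 100.0 * np.exp(-np.sum(rel**2, axis=-1))
    return (
        VolumeGrid(img, (1.0, 1.0, 1.0), HU),
        LabelVolume(mask, organ="blob"),
    )
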