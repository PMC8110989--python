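import numpy as np
import pytest

from wavenuc.synthetic import GroundTruth, NoiseSpec, SyntheticSpec, generate_dataset, render


@pytest.fixture(scope="session")
def clean_volume():
    """Noise-free 20-nucleus benchmark volume with its ground truth."""
    spec = SyntheticSpec(seed=0, noise=NoiseSpec(kind="none", base_white_variance=0.0))
    vol, truth = generate_dataset(spec)
    return vol, truth, spec


@pytest.fixture(scope="session")
def single_nucleus():
    """One centred nucleus (r = 9, I = 1000) in a 64x64x40 volume."""
    spec = SyntheticSpec(
        dims=(64, 64, 40), n_nuclei=1, radius=9, intensity=1000,
        radius_randomness=0, intensity_randomness=0,
    )
    truth = GroundTruth(centers=[[32.0, 32.0, 20.0]], radii=[9.0], intensities=[1000.0])
    vol = render(truth, spec)
    return vol, truth, spec


@pytest.fixture(scope="session")
def clean_segmentation(clean_volume):
    """Wavelet segmentation of the clean benchmark volume."""
    from wavenuc.segmentation import segment

    vol, truth, spec = clean_volume
    return segment(vol, radius=9), truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
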