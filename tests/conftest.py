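import numpy as np
import pytest

from hypercal.datasets import SpectralDataset, SyntheticSpec, generate_synthetic


@pytest.fixture(scope="session")
def default_dataset():
    """Full-size synthetic dataset at the study design (800 x 125)."""
    return generate_synthetic(SyntheticSpec(seed=11))


@pytest.fixture()
def small_dataset():
    """Quick dataset: 5 brands x 4 samples x 2 ROIs, 30 bands."""
    return generate_synthetic(
        SyntheticSpec(samples_per_brand=4, rois_per_sample=2, n_bands=30, seed=3)
    )


@pytest.fixture()
def toy_dataset():
    return SpectralDataset(
        wavelengths=np.array([400.0, 550.0, 700.0, 850.0, 1000.0]),
        reflectance=np.array([[0.5, 0.6, 0.7, 0.8, 0.9],
                              [0.4, 0.5, 0.6, 0.7, 0.8],
                              [0.45, 0.55, 0.65, 0.75, 0.85]]),
        analyte=np.array([19.0, 23.8, 28.0]),
        brand=np.array(["a", "b", "c"]),
        ids=np.array(["s1", "s2", "s3"]),
    )
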