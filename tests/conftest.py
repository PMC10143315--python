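import numpy as np
import pytest

from libsquant import GeneratorConfig, SpectraSet, SpectralAxis, SampleMeta, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One full-design synthetic experiment (192 x 1024), fixed seed."""
    return generate_dataset(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced design (2 brands) on the full axis — fast but structurally complete."""
    return generate_dataset(GeneratorConfig(design=(2, 8, 3), seed=3))


@pytest.fixture
def toy_spectra():
    """Tiny hand-built SpectraSet: 2 samples x 4 channels."""
    axis = SpectralAxis(np.array([210.0, 215.0, 220.0, 225.0]))
    metas = [
        SampleMeta("s1", 1, 1, 1, {"Cd": 0.5, "Cu": 3.0, "Pb": 0.2}),
        SampleMeta("s2", 1, 1, 2, {"Cd": 0.5, "Cu": 3.0, "Pb": 0.2}),
    ]
    X = np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0]])
    return SpectraSet(axis, X, metas)
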