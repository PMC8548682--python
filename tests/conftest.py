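import numpy as np
import pytest

from digitbone.synthetic import PhantomSpec, generate_digit_phantom


@pytest.fixture(scope="session")
def noiseless_spec() -> PhantomSpec:
    """Default regenerated-digit phantom with no blur and no noise."""
    return PhantomSpec(seed=11)


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_spec):
    return generate_digit_phantom(noiseless_spec)


@pytest.fixture(scope="session")
def label_density_volume(noiseless_phantom):
    """Per-voxel density field built directly from the ground-truth labels."""
    _, truth = noiseless_phantom
    density = np.zeros(truth.label_volume.shape, dtype=float)
    for lab, dens in truth.compartment_density.items():
        density[truth.label_volume == lab] = dens
    return density, truth
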