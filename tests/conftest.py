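import numpy as np
import pytest

from tdvpipe.synthdata import (IvimParams, PhantomSpec,
                               diffuse_spec_for_volume, generate_phantom)


@pytest.fixture(scope="session")
def focal_study():
    """Noiseless focal-dominant phantom on the default desk-scale grid."""
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def combined_study():
    """Noiseless combined (focal + diffuse) phantom."""
    return generate_phantom(
        PhantomSpec(pattern="combined", diffuse_involved_ml=50.0, seed=12))


@pytest.fixture(scope="session")
def diffuse_201_study():
    """Diffuse phantom whose true tumour volume is exactly 201 ml."""
    return generate_phantom(diffuse_spec_for_volume(201.0, seed=13))


@pytest.fixture(scope="session")
def normal_study():
    """Lesion-free phantom with unperfused marrow below the ADC band."""
    spec = PhantomSpec(pattern="normal", lesions=[],
                       ivim=IvimParams(f=0.0, dstar=20e-3), seed=14)
    return generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
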