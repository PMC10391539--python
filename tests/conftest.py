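import numpy as np
import pytest

from thorseg.phantom import PhantomConfig, generate_patient

#: Small phantom grid with valid mediastinal geometry (3 mm pixels).
TINY_PHANTOM = PhantomConfig(image_size=128, n_slices=6, spacing=(5.0, 3.0, 3.0),
                             carina_slice=2)


@pytest.fixture(scope="session")
def tiny_sample():
    return generate_patient(TINY_PHANTOM, patient_seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
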