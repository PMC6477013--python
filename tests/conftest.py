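import warnings

import numpy as np
import pytest

from kneeseg.licls import run_licls
from kneeseg.phantom import PhantomSpec, generate_phantom
from kneeseg.pipeline import run_pipeline


@pytest.fixture(scope="session")
def default_phantom():
    """The standard 96^3 two-bone phantom: bias, noise, ligament slab,
    thinning cortex (the package's stand-in for a clinical PDW volume)."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def pipeline_result(default_phantom):
    """Full pipeline run on the standard phantom, shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(default_phantom.volume)


@pytest.fixture(scope="session")
def bias_phantom_licls():
    """Level-set run on a noise-free phantom with a 40% bias field: the
    bias-recovery test condition."""
    truth = generate_phantom(PhantomSpec(noise_sd=0.0, bias_amplitude=0.4))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_licls(truth.volume)
    return truth, res


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
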