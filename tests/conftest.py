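import numpy as np
import pytest

import palsfv


@pytest.fixture(scope="session")
def default_settings():
    return palsfv.AcquisitionSettings()


@pytest.fixture(scope="session")
def mean_truth():
    """Three-component ground truth built from the reference mean row
    (tau3 = 1.83 ns, I3 = 9.01%)."""
    return palsfv.truth_from_sample(1.83, 9.01, seed=7)


@pytest.fixture(scope="session")
def simulated_spectrum(default_settings, mean_truth):
    return palsfv.simulate_spectrum(default_settings, mean_truth)


@pytest.fixture(scope="session")
def mean_fit(simulated_spectrum):
    """One three-component fit of the mean-truth spectrum, shared across
    tests that only inspect fit structure."""
    return palsfv.fit_components(simulated_spectrum)
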