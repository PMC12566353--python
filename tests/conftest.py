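import warnings

import numpy as np
import pytest

from spikechain import experiments as ex

# the front-end pole sits above Nyquist at the working rates by design; the
# aliasing warning is informative, not an error condition under test
warnings.filterwarnings("ignore", category=RuntimeWarning, module="spikechain")


@pytest.fixture(scope="session")
def stage_calibrations():
    """Distortion-level calibrations for all three stages (shared: ~10 s)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return ex.calibrate_all_stages(seed=1)


@pytest.fixture(scope="session")
def detection_sweep(stage_calibrations):
    """Scenario x level x 10-rep detection sweep on the reduced benchmark."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return ex.run_sweep(
            stage_calibrations,
            ex.BenchmarkConfig.reduced(),
            base_seed=42,
            n_reps=10,
            scenarios=("LNA", "PGA", "ADC", "all"),
            levels=(0, 1, 2, 3, 4),
        )


@pytest.fixture(scope="session")
def resolution_results():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return ex.resolution_sweep(bits=(8, 10, 12), base_seed=42, n_reps=10)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
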