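import numpy as np
import pytest

from pupilspan.synthetic import (CohortConfig, TrialParams,
                                 generate_trial_trace)


@pytest.fixture(scope="session")
def noiseless_config() -> CohortConfig:
    return CohortConfig(n_participants=1, seed=0, noise_sd=0.0,
                        blink_rate=0.0, gaze_noise_sd=0.0)


@pytest.fixture(scope="session")
def default_trial_params() -> TrialParams:
    return TrialParams(
        baseline_mm=5.0, constriction_latency_ms=450.0,
        constriction_amplitude_mm=0.4, constriction_peak_ms=900.0,
        dilation_rate_mm_per_s=0.8, condition="PRO", stimulus_side="right",
        srt_ms=230.0)


@pytest.fixture(scope="session")
def noiseless_trace(default_trial_params, noiseless_config):
    return generate_trial_trace(default_trial_params, noiseless_config,
                                rng=np.random.default_rng(0))
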