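import numpy as np
import pytest

import ipcwbrier as ib


@pytest.fixture(scope="session")
def spec10():
    """Study default predictor layout: 10 informative, compound symmetry 0.5."""
    return ib.PredictorSpec(p_informative=10, q_noise=0, pairwise_cov=0.5)


@pytest.fixture(scope="session")
def event_params():
    return ib.default_event_params()


@pytest.fixture(scope="session")
def small_cohort(event_params, spec10):
    """A 200-subject cohort with ~50% marginal exponential censoring."""
    return ib.generate_cohort(
        event_params, ib.default_censoring_params(50, "marginal"), spec10, 200, seed=101
    )


@pytest.fixture(scope="session")
def big_uncensored(event_params, spec10):
    """10^5 uncensored draws from the event process, for Monte-Carlo oracles."""
    Z, T = ib.sample_uncensored(event_params, spec10, 100_000, seed=202)
    return Z, T
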