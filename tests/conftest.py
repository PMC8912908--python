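import warnings

import pytest

from cardiosplice.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort shared by read-only tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(SimConfig(seed=11))


@pytest.fixture(scope="session")
def null_cohort():
    """No stage effects, shared cell composition across tissues."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(SimConfig(seed=12, n_stage_de=0,
                                         equal_composition=True))
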