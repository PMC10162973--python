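import numpy as np
import pytest

from invdecode.decoder import TrainingHyper
from invdecode.reduction import reduce_cohort
from invdecode.simulate import default_effects, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_cohort():
    """4 subjects x 8 trials/condition, default inversion effects, 200 Hz."""
    cohort = generate_cohort(4, 8, default_effects(), seed=11)
    return reduce_cohort(cohort)


@pytest.fixture(scope="session")
def fast_hyper():
    return TrainingHyper(lr=3e-3, max_epochs=30, patience=6)


@pytest.fixture(scope="session")
def trained_fold(tiny_cohort, fast_hyper):
    """One trained LOSO fold (3 seeds) of the tiny face cohort."""
    from invdecode.decoder import run_loso_protocol

    result = run_loso_protocol(
        tiny_cohort["face"], seeds=[0, 1, 2], hyper=fast_hyper, data_seed=5
    )
    return result.folds[0]
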