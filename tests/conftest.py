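import warnings

import numpy as np
import pytest

import fearcond as fc
from fearcond import ensembles as ens
from fearcond.traces import TraceMatrix, znormalize

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_config():
    """A reduced-scale experiment configuration for fast unit tests."""
    return fc.SyntheticConfig(n_neurons=40, rng_seed=7)


@pytest.fixture(scope="session")
def experiment(small_config):
    return fc.generate_experiment(small_config)


@pytest.fixture(scope="session")
def zscored(experiment):
    return znormalize(TraceMatrix.from_days(
        experiment.traces, "dff", experiment.config.frame_rate_hz))


@pytest.fixture(scope="session")
def cr_dataset(experiment, zscored):
    return ens.build_dataset(zscored, experiment.behavior, experiment.timeline,
                             "cr", phase="D4E")
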