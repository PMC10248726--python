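"""Shared fixtures: synthetic subjects and fitted capability models.

Model fitting is the expensive step, so fitted models are session scoped
and use a reduced number of hyperparameter restarts; the tests that depend
on them check structural properties that are insensitive to the restart
count.
"""

import warnings

import numpy as np
import pytest
from sklearn.exceptions import ConvergenceWarning

from fesreach.arm_model import ArmParameters, ArmState
from fesreach.muscle_capability import fit_capability_model
from fesreach.synthetic_subject import (
    make_ground_truth_subject,
    simulate_capability_experiment,
)

warnings.filterwarnings("ignore", category=ConvergenceWarning)


def pytest_configure(config):
    config.addinivalue_line(
        "filterwarnings", "ignore::sklearn.exceptions.ConvergenceWarning"
    )


@pytest.fixture(scope="session")
def params():
    return ArmParameters.from_body_mass()


@pytest.fixture(scope="session")
def subject():
    """Default synthetic subject (1 N force noise, weak region present)."""
    return make_ground_truth_subject(seed=1)


@pytest.fixture(scope="session")
def subject_noiseless():
    return make_ground_truth_subject(seed=1, noise_std=0.0)


@pytest.fixture(scope="session")
def dataset_noiseless(subject_noiseless):
    return simulate_capability_experiment(subject_noiseless, seed=3)


@pytest.fixture(scope="session")
def fitted_noiseless(dataset_noiseless):
    return fit_capability_model(dataset_noiseless, seed=0, n_restarts=2)


@pytest.fixture(scope="session")
def dataset(subject):
    return simulate_capability_experiment(subject, seed=3)


@pytest.fixture(scope="session")
def fitted(dataset):
    return fit_capability_model(dataset, seed=0, n_restarts=2)


@pytest.fixture(scope="session")
def rest_state(subject):
    return ArmState.at_rest(subject.equilibrium)
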