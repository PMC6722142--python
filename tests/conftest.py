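import numpy as np
import pytest

from her2traffic import reference_parameters
from her2traffic.inference import ConditionData, Dataset, TraffickingObjective
from her2traffic.synthetic import builtin_designs, schedule_for


@pytest.fixture(scope="session")
def main_design():
    return builtin_designs()[0]


@pytest.fixture(scope="session")
def validation_design():
    return builtin_designs()[1]


@pytest.fixture(scope="session")
def main_schedules(main_design):
    return {r.condition_id: schedule_for(r) for r in main_design}


@pytest.fixture(scope="session")
def model_b_truth():
    return reference_parameters("B")


@pytest.fixture(scope="session")
def model_a_truth():
    return reference_parameters("A")


def signal_dataset(params, model, schedules, sigma_rel=0.03, seed=None,
                   sigma=None):
    """Dataset of condition observables, optionally with Gaussian noise.

    ``sigma`` (absolute) overrides ``sigma_rel`` (relative to the largest
    observable). With ``seed=None`` the data are noise-free.
    """
    probe = Dataset(tuple(
        ConditionData(name, sched, 1.0, 1.0)
        for name, sched in schedules.items()))
    pred = TraffickingObjective(model, params, probe, []).predicted(params)
    if sigma is None:
        sigma = sigma_rel * float(np.max(pred))
    y = pred.copy()
    if seed is not None:
        y = y + np.random.default_rng(seed).normal(0.0, sigma, len(pred))
    return Dataset(tuple(
        ConditionData(name, sched, float(yy), float(sigma))
        for (name, sched), yy in zip(schedules.items(), y)))


@pytest.fixture(scope="session")
def noise_free_main_dataset(model_b_truth, main_schedules):
    return signal_dataset(model_b_truth, "B", main_schedules)
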