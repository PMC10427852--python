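import numpy as np
import pytest

from immunejm import (
    CohortSimulator,
    default_true_params,
    two_cause_recovery_params,
    two_cause_recovery_simulator,
)


@pytest.fixture(scope="session")
def default_cohort():
    """Small cohort under the calibrated model-I generative truth."""
    return CohortSimulator(n_subjects=80, random_state=17).sample()


@pytest.fixture(scope="session")
def default_truth():
    return default_true_params()


@pytest.fixture(scope="session")
def recovery_cohort():
    """Two-cause covariate-free cohort with known association coefficients."""
    sim = two_cause_recovery_simulator(n_subjects=300, random_state=23)
    return sim.sample(return_truth=True)


@pytest.fixture(scope="session")
def recovery_truth():
    return two_cause_recovery_params()


@pytest.fixture(scope="session")
def recovery_spec(recovery_truth):
    from immunejm.joint import CauseSpec, JointSpec

    return JointSpec(
        recovery_truth.longitudinal_spec(),
        (CauseSpec("c1", 1, ()), CauseSpec("c2", 2, ())),
        baseline_cuts=(2.0, 4.0), horizon=6.0)


@pytest.fixture(scope="session")
def recovery_fit(recovery_cohort, recovery_spec):
    """One joint fit on the two-cause recovery cohort, reused across tests."""
    from immunejm import JointModel

    tables, _ = recovery_cohort
    return JointModel(spec=recovery_spec, gh_order=7, gl_order=9,
                      compute_se=True).fit(tables)
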