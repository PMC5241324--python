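"""Shared fixtures.

The heavy simulation/recovery experiments are session-scoped so that the
acceptance checks and the module tests that need the same experiment run
it once.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def congruency_recovery():
    """20-seed parameter recovery at the congruency-analysis truth."""
    from antddm.recovery import recover_condition_parameters

    return recover_condition_parameters("congruency", n_seeds=20,
                                        n_per_condition=2000,
                                        seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def cue_recovery():
    """20-seed parameter recovery at the cue-analysis truth."""
    from antddm.recovery import recover_condition_parameters

    return recover_condition_parameters("cue", n_seeds=20,
                                        n_per_condition=2000,
                                        seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def group_recovery():
    """20+20 cohort recovery of the group-mean thresholds."""
    from antddm.recovery import recover_group_thresholds

    return recover_group_thresholds(n_per_group=20, n_per_condition=2000,
                                    seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def model_recovery_result():
    """BIC model recovery at the congruency-analysis truth."""
    from antddm.recovery import model_recovery

    return model_recovery(n_seeds=20, n_per_condition=2000, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def small_cohort():
    """A small single-session cohort with full ANT structure."""
    from antddm.synthetic import generate_cohort

    return generate_cohort(n_per_group=6, session_structure="single",
                           seed=FIXTURE_SEED)


def pool_median(per_seed, labels, name):
    """Median over seeds of the mean across ``labels`` of one parameter."""
    vals = np.mean([per_seed[lab][name] for lab in labels], axis=0)
    return float(np.median(vals))
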