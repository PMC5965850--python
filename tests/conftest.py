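import numpy as np
import pandas as pd
import pytest

from srsa.preprocessing import drop_first_fixation
from srsa.sr import participant_mean_srs, trial_srs
from srsa.state_spaces import build_state_space, map_all_scanpaths
from srsa.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def vertical_space():
    return build_state_space("vertical")


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort shared across tests (seed 0)."""
    return generate_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def cohort_sequences(default_cohort, vertical_space):
    fx = drop_first_fixation(default_cohort.fixations)
    return map_all_scanpaths(vertical_space, fx)


@pytest.fixture(scope="session")
def cohort_scores(default_cohort):
    return default_cohort.score_series("attention_deficit")


@pytest.fixture(scope="session")
def cohort_mean_srs(cohort_sequences):
    return participant_mean_srs(trial_srs(cohort_sequences, 0.7, 0.5))


@pytest.fixture(scope="session")
def small_cohort():
    """Cheap cohort for smoke/CLI tests."""
    return generate_cohort(
        CohortConfig(
            n_participants=10, n_trials=5, mean_fixations_per_trial=12, seed=3
        )
    )


def make_fixation_frame(rows):
    """rows: (pid, tid, order, x, y, dur)"""
    return pd.DataFrame(
        rows, columns=["participant_id", "trial_id", "order", "x", "y", "duration_ms"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
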