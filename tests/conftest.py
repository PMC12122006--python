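import numpy as np
import pytest

from remindbias.config import SimulationConfig
from remindbias.exclusions import apply_exclusions
from remindbias.factors import default_weights, score_factors
from remindbias.inference import build_cohort_table
from remindbias.scoring import score_cohort
from remindbias.simulate import make_fixture_cohort, simulate_cohort


@pytest.fixture(scope="session")
def weights():
    return default_weights()


@pytest.fixture(scope="session")
def small_cohort():
    """A 200-participant cohort at default (calibrated) settings."""
    return simulate_cohort(SimulationConfig(n_participants=200, seed=11))


@pytest.fixture(scope="session")
def small_scores(small_cohort):
    return score_cohort(small_cohort.trials, small_cohort.participants)


@pytest.fixture(scope="session")
def analysis_table(small_cohort, small_scores, weights):
    """Scored, filtered, factor-joined analysis table for the small cohort."""
    _, retained = apply_exclusions(
        small_scores,
        small_cohort.participants[["participant_id", "catch_response"]])
    fs = score_factors(small_cohort.items, weights)
    return build_cohort_table(retained, fs, small_cohort.participants)


@pytest.fixture(scope="session")
def fixture_cohort():
    return make_fixture_cohort()


@pytest.fixture(scope="session")
def fixture_scores(fixture_cohort):
    return score_cohort(fixture_cohort.trials, fixture_cohort.participants)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
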