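import numpy as np
import pytest

from somatomap import synthetic as syn
from somatomap import topography as topo


@pytest.fixture(scope="session")
def default_spec():
    return syn.CohortSpec()


@pytest.fixture(scope="session")
def profile_cohort(default_spec):
    """One synthetic imaging cohort (profiles + ground truth), seed-fixed."""
    return syn.gen_bin_profiles(default_spec, seed=11)


@pytest.fixture(scope="session")
def usage_cohort(default_spec):
    """One synthetic behavioural cohort (bouts, durations, truth)."""
    return syn.gen_usage_tables(default_spec, seed=12)


@pytest.fixture(scope="session")
def peak_table(profile_cohort):
    profiles, _ = profile_cohort
    return topo.peak_shift_table(profiles)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
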