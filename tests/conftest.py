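import numpy as np
import pytest

from toolplast import simulate as sim


@pytest.fixture(scope="session")
def small_cohort():
    """30-subject cohort spanning the puberty scale."""
    return sim.generate_cohort(30, seed=11)


@pytest.fixture(scope="session")
def effects16():
    """Study-condition effect specs with the crossing pinned at puberty 16."""
    return sim.default_effect_specs(16.0)


@pytest.fixture(scope="session")
def trial_table(small_cohort, effects16):
    """Long-format trial table for the small cohort (6 trials/session)."""
    return sim.generate_trial_parameters(small_cohort, effects16, n_trials=6, seed=21)


@pytest.fixture(scope="session")
def wide_table(trial_table):
    return sim.pivot_trials(trial_table)
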