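import numpy as np
import pandas as pd
import pytest

from affectrsa import GeneratorConfig, generate_dataset


def make_table(rows):
    """Build a trial table from (pid, trial_index, stim, val, aro, vcat, acat, scr, startle)."""
    cols = ["participant_id", "trial_index", "stimulus_id", "valence_rating",
            "arousal_rating", "valence_category", "arousal_category",
            "scr_amplitude", "startle_magnitude"]
    return pd.DataFrame(rows, columns=cols)


@pytest.fixture(scope="session")
def populations_table():
    return generate_dataset(GeneratorConfig.populations(12, seed=5, missing_rate=0.1))


@pytest.fixture(scope="session")
def fingerprint_table():
    return generate_dataset(GeneratorConfig.fingerprint(12, seed=5, missing_rate=0.1))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
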