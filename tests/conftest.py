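import numpy as np
import pytest

import micronet as mn


@pytest.fixture(scope="session")
def small_survey():
    """A 30-site survey with the default ground truth (shared, read-only)."""
    truth = mn.default_ground_truth(42)
    return mn.generate_survey(20, 10, truth, 42)


@pytest.fixture(scope="session")
def full_survey():
    """One survey at the study's sampling design (349 maize + 119 rice)."""
    truth = mn.default_ground_truth(7)
    return mn.generate_survey(349, 119, truth, 7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
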