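import numpy as np
import pytest

from foragescan.data_io import Pick, TrialRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trial(coords, participant="P1", condition="feature", set_size=60,
               trial=0, age=10.0, classes=None, is_target=None):
    """Build a TrialRecord from bare (n, 2) coordinates."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    classes = classes or [""] * n
    is_target = [True] * n if is_target is None else is_target
    picks = [Pick(order=i + 1, x=float(x), y=float(y),
                  item_class=classes[i], is_target=is_target[i])
             for i, (x, y) in enumerate(coords)]
    return TrialRecord(participant_id=participant, age_years=age,
                       condition=condition, set_size=set_size,
                       trial_index=trial, picks=picks)


@pytest.fixture
def trial_factory():
    return make_trial
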