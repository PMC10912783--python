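import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from sborg.records import SessionRecord, TRIAL_COLUMNS
from sborg.task import TaskConfig, generate_schedule
from sborg.cohort import AgentParams, simulate_session
from sborg.choice import ChoiceParams
from sborg.happiness import HappinessParams

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


def make_session(rows, subject_id="s01", group="ICD", med_state="off"):
    """Build a SessionRecord from compact per-trial tuples.

    Each row: (certain, g_low, g_high, choice, outcome, rating) with
    outcome/rating None where absent; prompts inferred from ratings.
    """
    recs = []
    for i, (cv, gl, gh, choice, outcome, rating) in enumerate(rows, start=1):
        recs.append({
            "trial_index": i, "certain_value": cv, "gamble_low": gl,
            "gamble_high": gh,
            "rating_prompt": rating is not None,
            "time_limit": 6, "choice": choice,
            "outcome": np.nan if outcome is None else float(outcome),
            "rating": np.nan if rating is None else float(rating),
        })
    return SessionRecord(subject_id, group, med_state,
                         pd.DataFrame(recs, columns=TRIAL_COLUMNS))


@pytest.fixture
def small_agent():
    return AgentParams(
        happiness=HappinessParams(w0=-1.0, w1=0.2, w2=0.2, w3=0.4,
                                  gamma=0.15, rating_noise_sd=0.5),
        choice=ChoiceParams(0.0, 2.0, -1.9, 0.0),
        timeout_prob=0.03)


@pytest.fixture
def small_session(small_agent):
    schedule = generate_schedule(TaskConfig(n_trials=120, seed=7))
    return simulate_session(small_agent, schedule,
                            np.random.default_rng(8))
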