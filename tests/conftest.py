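import numpy as np
import pytest

from ctxstop.race import BehavioralRecord, Outcome
from ctxstop.task_design import DesignConfig, Stimulus, generate_schedule


@pytest.fixture(scope="session")
def default_schedule():
    return generate_schedule(DesignConfig(rng_seed=11))


def make_stop_go_records(n_stop: int, n_go: int, context: int = 1) -> list[BehavioralRecord]:
    """Minimal trial records for EEG-stage tests: n_stop successful stops + n_go go trials."""
    records = []
    i = 0
    for _ in range(n_stop):
        records.append(
            BehavioralRecord(i, context, Stimulus.STIM1, True, 200.0, False, None, Outcome.STOP_SUCCESS)
        )
        i += 1
    for _ in range(n_go):
        records.append(
            BehavioralRecord(i, context, Stimulus.GO, False, None, True, 500.0, Outcome.GO_CORRECT)
        )
        i += 1
    return records


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
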