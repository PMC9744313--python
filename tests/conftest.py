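import numpy as np
import pytest

from crpseq import asrt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def patterns():
    return asrt.enumerate_patterns()


@pytest.fixture(scope="session")
def single_session_trials():
    """One labelled 4000-trial ASRT session (pattern 0, fixed seed)."""
    cfg = asrt.ScheduleConfig(
        session_lengths=(4000,), interference_session=99, alternation_session=99
    )
    pattern = asrt.enumerate_patterns()[0]
    return asrt.build_schedule(cfg, pattern, np.random.default_rng(7))


def make_stream(n_trials: int, seed: int = 0, pattern_id: int = 0):
    """Labelled single-session stream plus its event array."""
    cfg = asrt.ScheduleConfig(
        session_lengths=(n_trials,), interference_session=99, alternation_session=99
    )
    pattern = asrt.enumerate_patterns()[pattern_id]
    trials = asrt.build_schedule(cfg, pattern, np.random.default_rng(seed))
    events = np.array([t.event for t in trials])
    return trials, events, pattern
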