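import numpy as np
import pytest

from cuephot.events import Event, EventCode, EventLog, Phase


def make_log(events, phase=Phase.PRE_TRAINING, duration_s=200.0, **kw):
    """Hand-built event log from (time, code) pairs (kept time-sorted)."""
    evs = sorted((Event(float(t), EventCode(c)) for t, c in events),
                 key=lambda e: e.time_s)
    return EventLog(events=evs, phase=phase, duration_s=duration_s, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def rewarded_trial_log():
    """Three rewarded trials with retrieval latencies 3, 6 and 4.9 s."""
    rows = []
    for tone, npk, rec in [(10, 12, 15), (50, 52, 58), (90, 91, 95.9)]:
        rows += [
            (tone, EventCode.TONE_ON),
            (npk, EventCode.NP_CORRECT),
            (npk, EventCode.REWARD_ON),
            (npk + 2, EventCode.REWARD_OFF),
            (npk + 2, EventCode.TONE_OFF),
            (rec, EventCode.RECEPTACLE_ENTRY),
            (rec, EventCode.RECEPTACLE_LIGHT_OFF),
        ]
    return make_log(rows)
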