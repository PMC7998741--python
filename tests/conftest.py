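import numpy as np
import pandas as pd
import pytest

from pabcog import synthdata


@pytest.fixture(scope="session")
def profiles():
    return synthdata.default_profiles()


@pytest.fixture(scope="session")
def cognitive_profile():
    return synthdata.CognitiveProfile()


def make_stream(specs, start="2019-09-02 00:00:00", participant_id="P0001"):
    """Build an event frame from (activity, duration_min[, steps]) tuples."""
    t = pd.Timestamp(start)
    rows = []
    for spec in specs:
        activity, minutes = spec[0], spec[1]
        steps = spec[2] if len(spec) > 2 else 0
        rows.append(
            {
                "participant_id": participant_id,
                "start": t,
                "duration_s": minutes * 60.0,
                "activity": activity,
                "steps": steps,
            }
        )
        t += pd.Timedelta(seconds=minutes * 60.0)
    return pd.DataFrame(rows)


@pytest.fixture
def stream_builder():
    return make_stream
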