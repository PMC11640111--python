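import numpy as np
import pytest

from collarml import synthetic as syn
from collarml import preprocess as pp


@pytest.fixture(scope="session")
def short_cohort():
    """Three dogs with short events: fast but structurally complete."""
    cfg = syn.CohortConfig(n_dogs=3, duration_range_s=(1.5, 2.5), master_seed=7)
    return cfg, syn.generate_cohort(cfg)


@pytest.fixture(scope="session")
def normalized_sessions(short_cohort):
    _, sessions = short_cohort
    return [pp.znormalize_session(s)[0] for s in sessions]


def make_session(channel_funcs=None, duration_s=10.0, events=None,
                 dog_id="test") -> syn.Session:
    """Hand-built session whose channels follow given functions of time.

    channel_funcs maps modality -> callable t -> (n, C) values; defaults
    to zeros.  Used to craft signals with known analytic behavior.
    """
    channel_funcs = channel_funcs or {}
    streams = {}
    for name, (n_ch, rate) in syn.MODALITIES.items():
        n = int(np.floor(duration_s * rate)) + 1
        t = np.arange(n) / rate
        fn = channel_funcs.get(name)
        values = fn(t) if fn is not None else np.zeros((n, n_ch))
        if values.ndim == 1:
            values = values[:, None]
        streams[name] = syn.SensorStream(name, rate, t, values)
    events = events or [syn.StateEvent("Idle", 0.0, duration_s)]
    s = syn.Session(dog_id=dog_id, seed=0, streams=streams, events=events,
                    duration_s=duration_s)
    s.validate()
    return s
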