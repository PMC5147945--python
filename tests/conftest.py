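import numpy as np
import pandas as pd
import pytest

from conjuqc import ChannelSpec, EventTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(n=100, fsc=500.0, ssc=300.0, fl1=2.0, fl2=100.0, fl4=50.0,
               rng=None, meta=None):
    """Small helper: an EventTable with constant or jittered channels."""
    cols = {"FSC": fsc, "SSC": ssc, "FL1": fl1, "FL2": fl2, "FL4": fl4}
    data = {}
    for name, value in cols.items():
        if rng is None:
            data[name] = np.full(n, float(value))
        else:
            data[name] = np.exp(rng.normal(np.log(value), 0.2, n))
    spec = {c: ChannelSpec(linear=True) for c in cols}
    return EventTable(events=pd.DataFrame(data), meta=meta or {}, channel_spec=spec)


@pytest.fixture
def constant_table():
    return make_table(n=50)
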