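import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cryoleaf.thermal_io import ChannelMeta, SensorTable

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


def make_table(values_by_channel, roles=None, start="2019-07-10 18:00:00", interval_s=2.0, plant="plant_1"):
    """Build a SensorTable from {channel_id: 1-D array}; default role is leaf."""
    roles = roles or {}
    channels = list(values_by_channel)
    n = len(values_by_channel[channels[0]])
    meta = []
    for i, cid in enumerate(channels):
        role = roles.get(cid, "leaf")
        if role == "leaf":
            meta.append(ChannelMeta(cid, "leaf", plant_id=plant, leaf_id=f"leaf_{i}"))
        else:
            meta.append(ChannelMeta(cid, role))
    values = np.column_stack([np.asarray(values_by_channel[c], dtype=float) for c in channels])
    time = pd.date_range(start, periods=n, freq=pd.Timedelta(seconds=interval_s))
    return SensorTable(time=time, values=values, meta=meta, nominal_interval_s=interval_s)


@pytest.fixture(scope="session")
def small_campaign():
    """A 5-night default-parameter synthetic campaign with ground truth."""
    from cryoleaf.synthetic import CampaignConfig, simulate_campaign

    return simulate_campaign(CampaignConfig(n_nights=5, seed=11))
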