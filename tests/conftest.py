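import numpy as np
import pytest

from vasowave.preprocess import Segment
from vasowave.pulse_extraction import AmpSeries
from vasowave.synthetic_data import SimConfig


def make_series(values, grid_dt=0.5, mask=None, stage="raw", t0=0.0):
    return AmpSeries(grid_dt=grid_dt, values=np.asarray(values, dtype=float),
                     quality_mask=None if mask is None
                     else np.asarray(mask, dtype=bool),
                     stage_tag=stage, t0=t0)


def make_segment(values, grid_dt=0.5, mask=None, stage="raw", t0=0.0,
                 index=0, viable=True):
    amp = make_series(values, grid_dt, mask, stage, t0)
    return Segment(index=index, t_start=t0, t_end=t0 + amp.duration, amp=amp,
                   viable=viable)


@pytest.fixture
def quiet_sim():
    """Short night with every modulation source switched off."""
    return SimConfig(duration_s=120.0, resp_mod_depth=0.0, event_rate_per_h=0.0,
                     finger_noise_sd=0.0, wrist_noise_sd=0.0,
                     motion_artifact_rate_per_h=0.0, ibi_jitter_sd_s=0.0,
                     hourly_pause=False, clock_lag_s=0.0, seed=7)


@pytest.fixture
def short_sim():
    """10-minute clean night (no noise/motion) with events."""
    return SimConfig(duration_s=600.0, event_rate_per_h=18.0,
                     finger_noise_sd=0.0, wrist_noise_sd=0.0,
                     motion_artifact_rate_per_h=0.0, hourly_pause=False,
                     clock_lag_s=4.0, seed=11)
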