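"""Readers/writers for raw PPG recordings (wristband CSV, finger-sensor EDF).

Everything funnels into :class:`PPGRecord`: a uniform sample grid with a
per-sample gap mask (missing data are masked in place, never deleted, so
downstream segment indexing stays stable). Time is in seconds with t=0 at
the first sample of each record; intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from vasowave import _edf
from vasowave.errors import ConfigurationError, ParseError, SchemaError

#: accepted timestamp jitter, as a fraction of one sample period
_JITTER_TOL = 0.25

DEFAULT_COLUMN_MAP = {"time": "time_s", "ppg": "ppg"}


@dataclass
class PPGRecord:
    """One night of raw waveform samples from one device.

    Sample ``i`` lives at time ``start_time + i / sample_rate``. Gaps are
    represented by ``gap_mask`` (True = missing/invalid), keeping the grid
    uniform.
    """

    sample_rate: float
    samples: np.ndarray
    gap_mask: np.ndarray | None = None
    accel_magnitude: np.ndarray | None = None
    start_time: float = 0.0
    device_id: str = ""
    participant_id: str = ""
    night_id: str = ""

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ConfigurationError(f"sample_rate must be > 0, got {self.sample_rate}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.gap_mask is None:
            self.gap_mask = np.zeros(self.samples.shape, dtype=bool)
        else:
            self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if self.gap_mask.shape != self.samples.shape:
            raise ConfigurationError("gap_mask and samples must have equal length")
        if self.accel_magnitude is not None:
            self.accel_magnitude = np.asarray(self.accel_magnitude, dtype=float)
            if self.accel_magnitude.shape != self.samples.shape:
                raise ConfigurationError("accel_magnitude and samples must have equal length")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record span in seconds (grid extent, one period per sample)."""
        return self.n_samples / self.sample_rate

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sample_rate


def read_csv_record(path, column_map: dict[str, str] | None = None, *,
                    device_id: str = "", participant_id: str = "",
                    night_id: str = "") -> PPGRecord:
    """Read a wristband CSV export onto a uniform sample grid.

    ``column_map`` maps roles to column names: required ``time`` and
    ``ppg``; optional ``acc_x``/``acc_y``/``acc_z`` (tri-axial, combined to
    a magnitude) or a single ``accel`` magnitude column. Non-uniform
    timestamps are snapped to a grid at the median sampling interval; rows
    absent from the grid become masked gaps.
    """
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    try:
        frame = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise SchemaError(f"{path}: unreadable CSV ({exc})") from exc
    for role in ("time", "ppg"):
        name = cmap.get(role)
        if name is None or name not in frame.columns:
            raise SchemaError(f"{path}: required column for role {role!r} "
                              f"({name!r}) is missing")
    if len(frame) == 0:
        raise SchemaError(f"{path}: CSV contains no samples")

    t = frame[cmap["time"]].to_numpy(dtype=float)
    if np.any(~np.isfinite(t)):
        raise ParseError(f"{path}: non-finite timestamps")
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ParseError(f"{path}: time column must be strictly increasing")

    if len(t) == 1:
        dt = 1.0
    else:
        diffs = np.diff(t)
        # gaps inflate intervals; estimate the period from the cluster of
        # smallest diffs (true-period diffs under < 25% jitter)
        cluster = diffs[diffs <= 1.25 * np.min(diffs)]
        dt = float(np.median(cluster))
        if dt <= 0:
            raise ParseError(f"{path}: degenerate sampling interval")
    idx_f = (t - t[0]) / dt
    idx = np.rint(idx_f).astype(np.int64)
    if np.any(np.abs(idx_f - idx) > _JITTER_TOL):
        raise ParseError(f"{path}: timestamp jitter exceeds {_JITTER_TOL:.0%} "
                         "of one sample period")
    if len(idx) > 1 and np.any(np.diff(idx) <= 0):
        raise ParseError(f"{path}: timestamps collide on the uniform grid")

    n = int(idx[-1]) + 1
    samples = np.zeros(n)
    mask = np.ones(n, dtype=bool)
    samples[idx] = frame[cmap["ppg"]].to_numpy(dtype=float)
    mask[idx] = False
    mask |= ~np.isfinite(samples)
    samples[~np.isfinite(samples)] = 0.0

    accel = None
    if all(cmap.get(a) in frame.columns for a in ("acc_x", "acc_y", "acc_z")):
        axes = np.stack([frame[cmap[a]].to_numpy(dtype=float)
                         for a in ("acc_x", "acc_y", "acc_z")])
        mag = np.sqrt(np.sum(axes ** 2, axis=0))
        accel = np.zeros(n)
        accel[idx] = mag
    elif cmap.get("accel") in frame.columns:
        accel = np.zeros(n)
        accel[idx] = frame[cmap["accel"]].to_numpy(dtype=float)

    return PPGRecord(sample_rate=1.0 / dt, samples=samples, gap_mask=mask,
                     accel_magnitude=accel, device_id=device_id,
                     participant_id=participant_id, night_id=night_id)


def read_edf_record(path, channel_name: str = "PPG", *, device_id: str = "",
                    participant_id: str = "", night_id: str = "") -> PPGRecord:
    """Read one channel of an EDF file as a :class:`PPGRecord`.

    Samples flagged invalid in the file (sentinel digital value) become
    masked gaps. Only the requested channel is loaded; accelerometer data,
    if any, stays behind.
    """
    channels = _edf.read_edf(path)
    if channel_name not in channels:
        raise SchemaError(f"{path}: channel {channel_name!r} not found "
                          f"(available: {sorted(channels)})")
    ch = channels[channel_name]
    samples = np.array(ch.samples, dtype=float)
    samples[ch.mask] = 0.0
    return PPGRecord(sample_rate=float(ch.sample_rate), samples=samples,
                     gap_mask=ch.mask.copy(), device_id=device_id,
                     participant_id=participant_id, night_id=night_id)


def mask_hourly_pauses(record: PPGRecord, period_s: float = 3600.0,
                       pause_s: float = 300.0) -> PPGRecord:
    """Mask the periodic sync pauses of the wristband device.

    Each period ends with a pause: samples in ``[k*period - pause,
    k*period)`` for k = 1, 2, ... are masked. Returns a new record; input
    is untouched.
    """
    if not (period_s > pause_s > 0):
        raise ConfigurationError(
            f"need period_s > pause_s > 0, got period_s={period_s} pause_s={pause_s}")
    mask = record.gap_mask.copy()
    t = np.arange(record.n_samples) / record.sample_rate
    k = 1
    while k * period_s - pause_s < record.duration:
        win = (t >= k * period_s - pause_s) & (t < k * period_s)
        mask |= win
        k += 1
    return replace(record, samples=record.samples.copy(), gap_mask=mask,
                   accel_magnitude=None if record.accel_magnitude is None
                   else record.accel_magnitude.copy())
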