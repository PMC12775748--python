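"""Beat detection and the PPGamp beat-amplitude series.

The amplitude of a pulse is peak-to-trough: peak value minus the minimum of
the signal over the preceding inter-beat interval (the falling-edge trough).
Beat amplitudes are then placed at their peak times and linearly interpolated
onto a uniform grid (default 0.5 s) to form the ``AmpSeries`` all downstream
math consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from vasowave.errors import ConfigurationError, InsufficientDataError
from vasowave.ppg_io import PPGRecord

__all__ = ["BeatMeasure", "AmpSeries", "detect_beats", "build_amp_series"]

#: grid points farther than this from any detected beat are quality-masked
MAX_BEAT_GAP_S = 5.0

STAGES = ("raw", "capped", "normalized", "detrended_filtered")


@dataclass
class BeatMeasure:
    """One detected pulse: peak/trough geometry and peak-to-trough amplitude."""

    peak_time: float
    trough_time: float
    amplitude: float
    pulse_duration: float  # peak-to-peak interval to the next beat; NaN for last


@dataclass
class AmpSeries:
    """Uniformly gridded PPGamp with a per-point quality mask.

    ``quality_mask`` is True where a point is unusable. ``stage_tag`` tracks
    provenance through the preprocessing chain (raw -> capped -> normalized
    -> detrended_filtered).
    """

    grid_dt: float
    values: np.ndarray
    quality_mask: np.ndarray | None = None
    stage_tag: str = "raw"
    t0: float = 0.0
    accel: np.ndarray | None = None  # optional per-point accel magnitude (g)

    def __post_init__(self) -> None:
        if self.grid_dt <= 0:
            raise ConfigurationError(f"grid_dt must be > 0, got {self.grid_dt}")
        if self.stage_tag not in STAGES:
            raise ConfigurationError(f"unknown stage_tag {self.stage_tag!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.quality_mask is None:
            self.quality_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.quality_mask = np.asarray(self.quality_mask, dtype=bool)
        if self.quality_mask.shape != self.values.shape:
            raise ConfigurationError("quality_mask and values must have equal length")
        if self.accel is not None:
            self.accel = np.asarray(self.accel, dtype=float)
            if self.accel.shape != self.values.shape:
                raise ConfigurationError("accel and values must have equal length")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        return self.n * self.grid_dt

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) * self.grid_dt

    def copy(self) -> "AmpSeries":
        return replace(self, values=self.values.copy(),
                       quality_mask=self.quality_mask.copy(),
                       accel=None if self.accel is None else self.accel.copy())


def _interp_over_mask(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Fill masked samples by linear interpolation (edges held constant)."""
    if not mask.any():
        return x
    out = x.copy()
    idx = np.arange(x.size)
    good = ~mask
    if not good.any():
        return out
    out[mask] = np.interp(idx[mask], idx[good], x[good])
    return out


def _local_scale(x: np.ndarray, mask: np.ndarray, fs: float,
                 block_s: float = 10.0) -> np.ndarray:
    """Rolling amplitude scale: P90-P10 of the signal per ~10 s block."""
    n = x.size
    block = max(1, int(round(block_s * fs)))
    n_blocks = int(np.ceil(n / block))
    centers = np.empty(n_blocks)
    scales = np.empty(n_blocks)
    for b in range(n_blocks):
        lo, hi = b * block, min((b + 1) * block, n)
        centers[b] = (lo + hi - 1) / 2.0
        chunk = x[lo:hi][~mask[lo:hi]]
        if chunk.size >= 4:
            p10, p90 = np.percentile(chunk, [10, 90])
            scales[b] = p90 - p10
        else:
            scales[b] = np.nan
    if np.all(np.isnan(scales)):
        return np.zeros(n)
    med = np.nanmedian(scales)
    scales = np.where(np.isnan(scales), med, scales)
    return np.interp(np.arange(n), centers, scales)


def detect_beats(record: PPGRecord, hr_min_bpm: float = 40.0,
                 hr_max_bpm: float = 180.0,
                 prominence_frac: float = 0.3) -> list[BeatMeasure]:
    """Detect pulses and measure their peak-to-trough amplitudes.

    Peaks are local maxima separated by at least ``60/hr_max_bpm`` seconds
    whose prominence exceeds ``prominence_frac`` times the rolling amplitude
    scale. Each peak is paired with the signal minimum over the preceding
    inter-beat interval. Beats touching masked gaps are dropped.
    """
    if not 0 < hr_min_bpm < hr_max_bpm:
        raise ConfigurationError("need 0 < hr_min_bpm < hr_max_bpm")
    fs = record.sample_rate
    mask = record.gap_mask
    x_raw = record.samples
    n_valid = int(np.count_nonzero(~mask))
    if n_valid == 0:
        warnings.warn("record is fully masked; no beats detected", stacklevel=2)
        return []
    if n_valid / fs < 10.0:
        raise InsufficientDataError(
            f"need >= 10 s of unmasked signal, got {n_valid / fs:.1f} s")

    x = _interp_over_mask(x_raw, mask)
    scale = _local_scale(x, mask, fs)
    global_scale = float(np.max(scale))
    if global_scale <= 0:
        warnings.warn("flatline record; no beats detected", stacklevel=2)
        return []

    min_dist = max(1, int(round(60.0 / hr_max_bpm * fs)))
    peaks, props = sps.find_peaks(x, distance=min_dist,
                                  prominence=1e-9 * global_scale)
    keep = props["prominences"] >= prominence_frac * scale[peaks]
    peaks = peaks[keep]
    if peaks.size == 0:
        return []

    beats: list[BeatMeasure] = []
    # the first peak has no preceding inter-beat interval -> no trough
    for k, p in enumerate(peaks[1:], start=1):
        lo = peaks[k - 1]
        if lo >= p:
            continue
        seg = x[lo:p + 1]
        trough = lo + int(np.argmin(seg))
        if mask[trough:p + 1].any():
            continue
        amp = x[p] - x[trough]
        if amp <= 0:
            continue
        nxt = peaks[k + 1] if k + 1 < peaks.size else None
        beats.append(BeatMeasure(
            peak_time=p / fs,
            trough_time=trough / fs,
            amplitude=float(amp),
            pulse_duration=float((nxt - p) / fs) if nxt is not None else float("nan"),
        ))
    return beats


def build_amp_series(beats: list[BeatMeasure], grid_dt: float = 0.5,
                     t_end: float | None = None,
                     accel_times: np.ndarray | None = None,
                     accel_values: np.ndarray | None = None) -> AmpSeries:
    """Interpolate beat amplitudes onto a uniform grid starting at t=0.

    Grid points farther than 5 s from every beat peak are quality-masked.
    ``t_end`` extends/truncates the grid (defaults to the last beat time);
    if accelerometer samples are supplied they are interpolated onto the
    same grid for the signal-loss gate.
    """
    if len(beats) < 2:
        raise InsufficientDataError(f"need >= 2 beats, got {len(beats)}")
    peak_t = np.array([b.peak_time for b in beats])
    amps = np.array([b.amplitude for b in beats])
    order = np.argsort(peak_t)
    peak_t, amps = peak_t[order], amps[order]

    # half-open grid [0, end): a t_end that is an exact multiple of grid_dt
    # yields exactly end/grid_dt points
    if t_end is None:
        end = float(peak_t[-1]) + grid_dt
    else:
        end = float(t_end)
    n = max(2, int(np.floor(end / grid_dt + 1e-9)))
    t = np.arange(n) * grid_dt
    values = np.interp(t, peak_t, amps)

    # distance from each grid point to the nearest beat peak
    j = np.searchsorted(peak_t, t)
    d_right = np.where(j < peak_t.size, peak_t[np.minimum(j, peak_t.size - 1)] - t,
                       np.inf)
    d_left = np.where(j > 0, t - peak_t[np.maximum(j - 1, 0)], np.inf)
    mask = np.minimum(d_left, d_right) > MAX_BEAT_GAP_S

    accel = None
    if accel_times is not None and accel_values is not None:
        accel = np.interp(t, np.asarray(accel_times, dtype=float),
                          np.asarray(accel_values, dtype=float))
    return AmpSeries(grid_dt=grid_dt, values=values, quality_mask=mask,
                     stage_tag="raw", accel=accel)
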