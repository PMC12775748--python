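"""Seeded generator of paired finger/wrist nocturnal PPG with ground truth.

The model shares one latent vasomotor drive between devices: a unit-amplitude
pulse train whose beat-to-beat amplitude is modulated multiplicatively by
(i) respiration, (ii) transient vasoconstriction dips with known times and
depths, and is then observed per device with its own gain, additive noise,
clock offset, sampling rate, periodic sync pauses and motion artifacts.

Each simulated beat's peak-to-trough amplitude equals the latent envelope at
the beat's peak time, so detector output can be scored against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from vasowave.errors import ConfigurationError, FormatError
from vasowave.ppg_io import PPGRecord, mask_hourly_pauses
from vasowave import _edf

__all__ = ["SimConfig", "GroundTruth", "simulate_night", "write_fixture",
           "latent_envelope"]

# pulse template: fast systolic rise + dicrotic bump, zero at both beat edges
_TPL_N = 4096
_TPL_U = np.linspace(0.0, 1.0, _TPL_N)


def _make_template() -> np.ndarray:
    u = _TPL_U
    lobes = (np.exp(-0.5 * ((u - 0.18) / 0.07) ** 2)
             + 0.30 * np.exp(-0.5 * ((u - 0.48) / 0.11) ** 2))
    taper = np.sin(np.pi * u) ** 0.5
    g = lobes * taper
    g -= g.min()
    return g / g.max()


_TEMPLATE = _make_template()
_U_PEAK = float(_TPL_U[int(np.argmax(_TEMPLATE))])


@dataclass
class SimConfig:
    """Parameters of one simulated night (all rates/durations in SI units)."""

    duration_s: float = 4 * 3600.0
    pulse_rate_bpm: float = 55.0
    ibi_jitter_sd_s: float = 0.03
    resp_freq_hz: float = 0.25
    resp_mod_depth: float = 0.10
    event_rate_per_h: float = 8.0
    event_depth_mean: float = 0.40
    event_depth_sd: float = 0.12
    event_depth_bounds: tuple[float, float] = (0.05, 0.90)
    event_duration_mean_s: float = 20.0
    event_duration_sd_s: float = 8.0
    event_duration_bounds_s: tuple[float, float] = (5.0, 60.0)
    event_shape: str = "cosine"  # "cosine" (smooth edges) or "rect" (closed-form)
    min_event_gap_s: float = 20.0
    finger_gain: float = 2.0
    wrist_gain: float = 0.6
    finger_noise_sd: float = 0.01
    wrist_noise_sd: float = 0.03
    clock_lag_s: float = -7.0
    hourly_pause: bool = True
    pause_period_s: float = 3600.0
    pause_len_s: float = 300.0
    motion_artifact_rate_per_h: float = 4.0
    motion_burst_len_s: float = 3.0
    finger_sample_rate: float = 100.0
    wrist_sample_rate: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be > 0")
        if self.pulse_rate_bpm <= 0:
            raise ConfigurationError("pulse_rate_bpm must be > 0")
        if not (0 <= self.resp_mod_depth < 1):
            raise ConfigurationError("resp_mod_depth must be in [0, 1)")
        lo, hi = self.event_depth_bounds
        if not (0 < lo < hi < 1):
            raise ConfigurationError("event_depth_bounds must satisfy 0 < lo < hi < 1")
        dlo, dhi = self.event_duration_bounds_s
        if not (0 < dlo < dhi):
            raise ConfigurationError("event_duration_bounds_s must satisfy 0 < lo < hi")
        if abs(self.clock_lag_s) > 30:
            raise ConfigurationError("clock_lag_s must lie within [-30, +30] s")
        if self.event_shape not in ("cosine", "rect"):
            raise ConfigurationError(f"unknown event_shape {self.event_shape!r}")
        if self.hourly_pause and not (self.pause_period_s > self.pause_len_s > 0):
            raise ConfigurationError("need pause_period_s > pause_len_s > 0")
        for name in ("finger_gain", "wrist_gain", "finger_sample_rate",
                     "wrist_sample_rate"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("event_rate_per_h", "finger_noise_sd", "wrist_noise_sd",
                     "motion_artifact_rate_per_h", "event_depth_sd",
                     "event_duration_sd_s", "ibi_jitter_sd_s"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """What was injected: events, clock lag, and masked gap windows."""

    events: list[tuple[float, float, float]]  # (start_s, end_s, depth)
    true_lag_s: float
    gap_intervals: list[tuple[float, float]] = field(default_factory=list)
    beat_peak_times: np.ndarray | None = None

    def to_json(self, path) -> None:
        payload = {
            "events": [{"start_s": s, "end_s": e, "depth": d}
                       for s, e, d in self.events],
            "true_lag_s": self.true_lag_s,
            "gap_intervals": [{"start_s": s, "end_s": e}
                              for s, e in self.gap_intervals],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               bounds: tuple[float, float], size: int) -> np.ndarray:
    lo, hi = bounds
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _draw_events(cfg: SimConfig, rng: np.random.Generator
                 ) -> list[tuple[float, float, float]]:
    n = rng.poisson(cfg.event_rate_per_h * cfg.duration_s / 3600.0)
    if n == 0:
        return []
    durations = _truncnorm(rng, cfg.event_duration_mean_s,
                           cfg.event_duration_sd_s,
                           cfg.event_duration_bounds_s, n)
    depths = _truncnorm(rng, cfg.event_depth_mean, cfg.event_depth_sd,
                        cfg.event_depth_bounds, n)
    placed: list[tuple[float, float, float]] = []
    gap = cfg.min_event_gap_s
    for dur, depth in zip(durations, depths):
        lo = gap
        hi = cfg.duration_s - dur - gap
        if hi <= lo:
            continue
        for _ in range(500):
            start = rng.uniform(lo, hi)
            end = start + dur
            if all(end + gap <= s or start >= e + gap for s, e, _ in placed):
                placed.append((float(start), float(end), float(depth)))
                break
    placed.sort()
    return placed


def _event_factor(times: np.ndarray, events, shape: str) -> np.ndarray:
    """Multiplicative dip factor of the vasomotor drive at ``times``."""
    factor = np.ones_like(times, dtype=float)
    for start, end, depth in events:
        dur = end - start
        inside = (times >= start) & (times < end)
        if not np.any(inside):
            continue
        if shape == "rect":
            w = np.ones(int(np.count_nonzero(inside)))
        else:
            ramp = min(3.0, dur / 4.0)
            rel = times[inside] - start
            w = np.ones(rel.shape)
            head = rel < ramp
            tail = rel > dur - ramp
            w[head] = 0.5 * (1 - np.cos(np.pi * rel[head] / ramp))
            w[tail] = 0.5 * (1 - np.cos(np.pi * (dur - rel[tail]) / ramp))
        factor[inside] -= depth * w
    return factor


def latent_envelope(cfg: SimConfig, truth: GroundTruth,
                    times: np.ndarray) -> np.ndarray:
    """Latent beat-amplitude envelope (drive time base, unit gain)."""
    times = np.asarray(times, dtype=float)
    env = np.ones_like(times)
    if cfg.resp_mod_depth > 0:
        env *= 1.0 + cfg.resp_mod_depth * np.sin(
            2 * np.pi * cfg.resp_freq_hz * times)
    env *= _event_factor(times, truth.events, cfg.event_shape)
    return env


def _beat_grid(cfg: SimConfig, rng: np.random.Generator,
               t_lo: float, t_hi: float) -> np.ndarray:
    """Beat start times covering [t_lo, t_hi] with jittered inter-beat intervals."""
    mean_ibi = 60.0 / cfg.pulse_rate_bpm
    n = int(np.ceil((t_hi - t_lo) / mean_ibi)) + 4
    ibis = mean_ibi + rng.normal(0.0, cfg.ibi_jitter_sd_s, size=n)
    ibis = np.clip(ibis, 0.25, 3.0)
    starts = t_lo + np.concatenate([[0.0], np.cumsum(ibis)])
    return starts[starts <= t_hi + mean_ibi]


def _sample_waveform(physio_t: np.ndarray, beat_starts: np.ndarray,
                     beat_amp: np.ndarray) -> np.ndarray:
    """Evaluate the pulse train at arbitrary physiological times."""
    j = np.searchsorted(beat_starts, physio_t, side="right") - 1
    j = np.clip(j, 0, len(beat_starts) - 2)
    ibi = beat_starts[j + 1] - beat_starts[j]
    u = np.clip((physio_t - beat_starts[j]) / ibi, 0.0, 1.0)
    return beat_amp[j] * np.interp(u, _TPL_U, _TEMPLATE)


def simulate_night(cfg: SimConfig) -> tuple[PPGRecord, PPGRecord, GroundTruth]:
    """Simulate one night for both devices plus the injected ground truth.

    Returns ``(finger, wrist, truth)``. The wrist record observes the shared
    drive delayed by ``cfg.clock_lag_s`` (wrist-local time minus drive time),
    scaled by its gain, with independent noise, motion bursts registered on
    the accelerometer channel, and the periodic sync pause masked out.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_ev, rng_beat, rng_f, rng_w, rng_mot = (
        np.random.default_rng(s) for s in ss.spawn(5))

    events = _draw_events(cfg, rng_ev)
    truth = GroundTruth(events=events, true_lag_s=cfg.clock_lag_s)

    pad = 35.0 + 60.0 / cfg.pulse_rate_bpm
    beat_starts = _beat_grid(cfg, rng_beat, -pad, cfg.duration_s + pad)
    ibi = np.diff(beat_starts)
    peak_times = beat_starts[:-1] + _U_PEAK * ibi
    beat_amp = latent_envelope(cfg, truth, peak_times)
    truth.beat_peak_times = peak_times[(peak_times >= 0)
                                       & (peak_times < cfg.duration_s)]

    def observe(sample_rate: float, gain: float, noise_sd: float,
                lag: float, rng: np.random.Generator) -> np.ndarray:
        n = int(round(cfg.duration_s * sample_rate))
        t = np.arange(n) / sample_rate
        sig = gain * _sample_waveform(t - lag, beat_starts, beat_amp)
        if noise_sd > 0:
            sig = sig + rng.normal(0.0, noise_sd * gain, size=n)
        return sig

    finger_sig = observe(cfg.finger_sample_rate, cfg.finger_gain,
                         cfg.finger_noise_sd, 0.0, rng_f)
    wrist_sig = observe(cfg.wrist_sample_rate, cfg.wrist_gain,
                        cfg.wrist_noise_sd, cfg.clock_lag_s, rng_w)

    # motion artifacts: PPG spikes wherever the simulated accelerometer bursts
    n_w = wrist_sig.size
    t_w = np.arange(n_w) / cfg.wrist_sample_rate
    accel = np.full(n_w, 0.01) + rng_mot.normal(0.0, 0.003, size=n_w)
    n_bursts = rng_mot.poisson(cfg.motion_artifact_rate_per_h
                               * cfg.duration_s / 3600.0)
    for _ in range(n_bursts):
        c = rng_mot.uniform(0.0, cfg.duration_s)
        half = cfg.motion_burst_len_s / 2.0
        sel = (t_w >= c - half) & (t_w < c + half)
        k = int(np.count_nonzero(sel))
        if k == 0:
            continue
        accel[sel] += rng_mot.uniform(0.3, 1.0)
        wrist_sig[sel] += rng_mot.normal(0.0, 2.0 * cfg.wrist_gain, size=k)
    accel = np.abs(accel)

    finger = PPGRecord(sample_rate=cfg.finger_sample_rate, samples=finger_sig,
                       device_id="finger")
    wrist = PPGRecord(sample_rate=cfg.wrist_sample_rate, samples=wrist_sig,
                      accel_magnitude=accel, device_id="wrist")

    if cfg.hourly_pause:
        wrist = mask_hourly_pauses(wrist, cfg.pause_period_s, cfg.pause_len_s)
        k = 1
        while k * cfg.pause_period_s - cfg.pause_len_s < cfg.duration_s:
            start = k * cfg.pause_period_s - cfg.pause_len_s
            truth.gap_intervals.append(
                (start, min(k * cfg.pause_period_s, cfg.duration_s)))
            k += 1
    return finger, wrist, truth


def write_fixture(record: PPGRecord, path, format: str = "csv") -> None:
    """Write a record to disk in a format the readers round-trip.

    ``csv``: ``time_s,ppg[,acc_x,acc_y,acc_z]``, masked samples written as
    absent rows (signal loss). ``edf``: one PPG channel, masked samples as
    invalid sentinels; requires an integer sampling rate.
    """
    if record.n_samples == 0 or bool(np.all(record.gap_mask)):
        raise FormatError("refusing to write a record with no valid samples")
    if format == "csv":
        keep = ~record.gap_mask
        t = np.arange(record.n_samples) / record.sample_rate
        cols = {"time_s": t[keep], "ppg": record.samples[keep]}
        if record.accel_magnitude is not None:
            cols["acc_x"] = record.accel_magnitude[keep]
            cols["acc_y"] = np.zeros(int(np.count_nonzero(keep)))
            cols["acc_z"] = np.zeros(int(np.count_nonzero(keep)))
        import pandas as pd

        pd.DataFrame(cols).to_csv(path, index=False)
    elif format == "edf":
        if record.sample_rate != int(record.sample_rate):
            raise FormatError(
                f"EDF fixture requires an integer sample rate, got {record.sample_rate}")
        ch = _edf.EdfChannel(label="PPG", sample_rate=int(record.sample_rate),
                             samples=record.samples, mask=record.gap_mask,
                             physical_dimension="au")
        _edf.write_edf(path, [ch])
    else:
        raise FormatError(f"unsupported fixture format {format!r}")
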