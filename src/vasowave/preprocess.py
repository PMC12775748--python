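"""From raw PPGamp to the "clean" signal: segmentation and conditioning.

Nights are divided into consecutive 15-minute segments. Each viable segment
is gated for signal loss and motion, has outliers capped at the segment's
98th percentile, is normalized to its 95th percentile, linearly detrended,
and low-pass filtered below 0.15 Hz (zero phase) to remove respiratory
influence. Pipeline order is fixed: gate -> cap -> normalize ->
detrend_and_filter; all statistics use unmasked points only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from vasowave.errors import ConfigurationError
from vasowave.pulse_extraction import AmpSeries, _interp_over_mask

__all__ = ["Segment", "segment_night", "gate_signal_loss", "cap_outliers",
           "normalize", "detrend_and_filter", "clean_segment"]

SEGMENT_LEN_S = 900.0
#: masked runs at most this long are interpolated across after gating
MAX_INTERP_GAP_S = 5.0


@dataclass
class Segment:
    """One nominal 15-minute slice of a night's AmpSeries."""

    index: int
    t_start: float
    t_end: float
    amp: AmpSeries
    viable: bool = True
    quality_notes: list[str] = field(default_factory=list)
    pre_detrend_mean: float | None = None  # level removed by detrending

    @property
    def interval(self) -> tuple[float, float]:
        return (self.t_start, self.t_end)

    def copy(self) -> "Segment":
        return replace(self, amp=self.amp.copy(),
                       quality_notes=list(self.quality_notes))


def segment_night(series: AmpSeries, seg_len_s: float = SEGMENT_LEN_S
                  ) -> list[Segment]:
    """Tile the night into consecutive segments of nominal length.

    A trailing remainder shorter than ``seg_len_s`` is emitted flagged
    ``short`` and non-viable so nightly bookkeeping stays complete.
    """
    if seg_len_s <= 0:
        raise ConfigurationError("seg_len_s must be > 0")
    if series.n == 0:
        return []
    n_per = int(round(seg_len_s / series.grid_dt))
    if n_per < 1:
        raise ConfigurationError("seg_len_s shorter than one grid step")
    segments: list[Segment] = []
    n_full = series.n // n_per
    for i in range(n_full):
        lo, hi = i * n_per, (i + 1) * n_per
        segments.append(_slice(series, i, lo, hi))
    rem = series.n - n_full * n_per
    if rem > 0:
        seg = _slice(series, n_full, n_full * n_per, series.n)
        seg.viable = False
        seg.quality_notes.append("short")
        segments.append(seg)
    return segments


def _slice(series: AmpSeries, index: int, lo: int, hi: int) -> Segment:
    amp = AmpSeries(grid_dt=series.grid_dt, values=series.values[lo:hi].copy(),
                    quality_mask=series.quality_mask[lo:hi].copy(),
                    stage_tag=series.stage_tag,
                    t0=series.t0 + lo * series.grid_dt,
                    accel=None if series.accel is None
                    else series.accel[lo:hi].copy())
    return Segment(index=index, t_start=amp.t0,
                   t_end=series.t0 + hi * series.grid_dt, amp=amp)


def gate_signal_loss(segment: Segment, max_masked_frac: float = 0.2,
                     accel_thresh: float = 0.1) -> Segment:
    """Automated stand-in for visual signal-loss screening.

    The segment is marked non-viable if the masked fraction or the
    accelerometer-flagged fraction exceeds ``max_masked_frac``. Otherwise
    masked runs no longer than 5 s are interpolated across; longer runs
    stay masked.
    """
    seg = segment.copy()
    mask = seg.amp.quality_mask
    n = seg.amp.n
    if n == 0:
        return seg
    masked_frac = float(np.count_nonzero(mask)) / n
    if masked_frac > max_masked_frac:
        seg.viable = False
        if "signal_loss" not in seg.quality_notes:
            seg.quality_notes.append("signal_loss")
        return seg
    if seg.amp.accel is not None:
        accel_frac = float(np.count_nonzero(seg.amp.accel > accel_thresh)) / n
        if accel_frac > max_masked_frac:
            seg.viable = False
            if "motion" not in seg.quality_notes:
                seg.quality_notes.append("motion")
            return seg
    # interpolate only short masked runs
    max_run = int(round(MAX_INTERP_GAP_S / seg.amp.grid_dt))
    new_mask = mask.copy()
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i <= max_run and i > 0 and j < n:
                new_mask[i:j] = False
            i = j
        else:
            i += 1
    seg.amp.values = _interp_over_mask(seg.amp.values, mask)
    seg.amp.quality_mask = new_mask
    return seg


def _require_stage(segment: Segment, allowed: tuple[str, ...], op: str) -> None:
    if segment.amp.stage_tag not in allowed:
        raise ConfigurationError(
            f"{op} expects stage in {allowed}, got {segment.amp.stage_tag!r}")


def cap_outliers(segment: Segment, pctl: float = 98.0) -> Segment:
    """Replace values above the segment's ``pctl`` percentile with it.

    The percentile is computed over pre-capping unmasked values only.
    """
    if not segment.viable:
        return segment.copy()
    _require_stage(segment, ("raw", "capped"), "cap_outliers")
    seg = segment.copy()
    valid = ~seg.amp.quality_mask
    if valid.any():
        cap = float(np.percentile(seg.amp.values[valid], pctl))
        over = valid & (seg.amp.values > cap)
        seg.amp.values[over] = cap
    seg.amp.stage_tag = "capped"
    return seg


def normalize(segment: Segment, pctl: float = 95.0) -> Segment:
    """Divide by the segment's ``pctl`` percentile (unmasked values).

    Afterwards the segment's P``pctl`` equals 1 exactly, removing device
    scale. A nonpositive percentile (degenerate flatline) marks the segment
    non-viable instead of dividing.
    """
    if not segment.viable:
        return segment.copy()
    _require_stage(segment, ("capped", "normalized"), "normalize")
    seg = segment.copy()
    valid = ~seg.amp.quality_mask
    denom = float(np.percentile(seg.amp.values[valid], pctl)) if valid.any() else 0.0
    if denom <= 0:
        seg.viable = False
        if "degenerate" not in seg.quality_notes:
            seg.quality_notes.append("degenerate")
        return seg
    seg.amp.values = seg.amp.values / denom
    seg.amp.stage_tag = "normalized"
    return seg


def detrend_and_filter(segment: Segment, cutoff_hz: float = 0.15,
                       order: int = 4) -> Segment:
    """Remove the least-squares line, then zero-phase low-pass below cutoff.

    The pre-detrend mean of unmasked values is stored on the segment
    (``pre_detrend_mean``) so event detection can re-offset the zero-mean
    output back to a positive level.
    """
    if not segment.viable:
        return segment.copy()
    _require_stage(segment, ("normalized",), "detrend_and_filter")
    seg = segment.copy()
    dt = seg.amp.grid_dt
    nyq = 0.5 / dt
    if cutoff_hz >= nyq:
        raise ConfigurationError(
            f"cutoff {cutoff_hz} Hz at or above Nyquist {nyq} Hz")
    n = seg.amp.n
    valid = ~seg.amp.quality_mask
    if not valid.any():
        seg.viable = False
        seg.quality_notes.append("signal_loss")
        return seg
    seg.pre_detrend_mean = float(np.mean(seg.amp.values[valid]))

    x = _interp_over_mask(seg.amp.values, seg.amp.quality_mask)
    idx = np.arange(n, dtype=float)
    coef = np.polyfit(idx[valid], x[valid], 1)
    x = x - np.polyval(coef, idx)

    b, a = sps.butter(order, cutoff_hz / nyq, btype="low")
    padlen = 3 * (max(len(a), len(b)) - 1)
    if n <= padlen:
        seg.viable = False
        seg.quality_notes.append("short")
        return seg
    seg.amp.values = sps.filtfilt(b, a, x)
    seg.amp.stage_tag = "detrended_filtered"
    return seg


def clean_segment(segment: Segment, *, max_masked_frac: float = 0.2,
                  accel_thresh: float = 0.1, cap_pctl: float = 98.0,
                  norm_pctl: float = 95.0, cutoff_hz: float = 0.15) -> Segment:
    """Run the full conditioning chain in its fixed order."""
    seg = gate_signal_loss(segment, max_masked_frac, accel_thresh)
    seg = cap_outliers(seg, cap_pctl)
    seg = normalize(seg, norm_pctl)
    seg = detrend_and_filter(seg, cutoff_hz)
    return seg
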