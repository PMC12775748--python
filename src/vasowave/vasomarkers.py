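"""Vasoconstriction markers from the clean PPGamp signal.

Two quantities are computed per night:

* ``Mvasoc`` — events are detected as drops of the PPGamp below
  ``(1 - depth_thresh)`` times the mean of the preceding 15-second baseline
  window, lasting until the signal returns to that baseline. Each event's
  magnitude is ``(drop_area / duration) / baseline``; the nightly median is
  the summary index.
* ``PPGampCV`` — the coefficient of variation (sample SD / mean) of PPGamp
  over a 5-minute sliding window evaluated every 30 seconds.

Event detection and CV both run on the detrended, respiratory-filtered
signal re-offset by the segment's pre-detrend mean, so levels stay positive
and relative thresholds remain meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from vasowave.errors import ConfigurationError, InsufficientDataError
from vasowave.pulse_extraction import AmpSeries
from vasowave.preprocess import Segment

__all__ = ["VasoEvent", "CVSeries", "NightSummary", "detect_vaso_events",
           "mvasoc_of_event", "ppgamp_cv", "summarize_night",
           "segment_level_values", "assemble_night_series"]


@dataclass
class VasoEvent:
    """One detected vasoconstriction event."""

    start: float
    end: float
    baseline: float
    drop_area: float
    mvasoc: float
    flags: list[str] = field(default_factory=list)

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class CVSeries:
    """PPGampCV on a regular grid of window centers."""

    window_s: float
    step_s: float
    centers: np.ndarray
    values: np.ndarray
    valid_mask: np.ndarray  # True = valid point

    @property
    def n(self) -> int:
        return int(self.centers.size)


@dataclass
class NightSummary:
    """Per-night, per-device tallies and medians of both markers."""

    night_id: str
    device_id: str
    n_events: int
    median_mvasoc: float  # NaN when no events were detected
    median_cv: float  # NaN when no valid CV points
    n_viable_segments: int


def mvasoc_of_event(drop_area: float, duration: float, baseline: float) -> float:
    """Magnitude of vasoconstriction: (drop area / duration) / baseline."""
    if duration <= 0:
        raise ConfigurationError(f"duration must be > 0, got {duration}")
    if baseline <= 0:
        raise ConfigurationError(f"baseline must be > 0, got {baseline}")
    if drop_area < 0:
        raise ConfigurationError(f"drop_area must be >= 0, got {drop_area}")
    return (drop_area / duration) / baseline


def segment_level_values(segment: Segment) -> np.ndarray:
    """Segment values re-offset to a positive level.

    For a detrended/filtered segment the stored pre-detrend mean is added
    back; earlier stages are returned as-is.
    """
    x = segment.amp.values
    if segment.amp.stage_tag == "detrended_filtered" and segment.pre_detrend_mean:
        return x + segment.pre_detrend_mean
    return x


def _rolling_baseline(x: np.ndarray, valid: np.ndarray, w: int) -> np.ndarray:
    """Mean of valid points over the preceding ``w`` samples (prefix if fewer)."""
    xv = np.where(valid, x, 0.0)
    cs = np.concatenate([[0.0], np.cumsum(xv)])
    cn = np.concatenate([[0], np.cumsum(valid.astype(np.int64))])
    i = np.arange(x.size)
    lo = np.maximum(i - w, 0)
    num = cs[i] - cs[lo]
    cnt = cn[i] - cn[lo]
    with np.errstate(invalid="ignore"):
        return np.where(cnt > 0, num / np.maximum(cnt, 1), np.nan)


def detect_vaso_events(segment: Segment, baseline_s: float = 15.0,
                       depth_thresh: float = 0.15,
                       min_dur_s: float = 3.0) -> list[VasoEvent]:
    """Detect vasoconstriction events within one viable segment.

    Onset: first point below ``baseline * (1 - depth_thresh)`` where the
    baseline is the mean of the preceding 15 s (frozen at onset; the
    available prefix is used, and the event flagged, when the onset is
    closer than 15 s to the segment start). Offset: return to baseline, a
    masked run, or the segment boundary (flagged ``truncated``). Events
    shorter than ``min_dur_s`` are discarded. The drop area is the
    trapezoidal integral of ``max(0, baseline - PPGamp)``.
    """
    if not (0 < depth_thresh < 1):
        raise ConfigurationError("depth_thresh must be in (0, 1)")
    if not segment.viable:
        return []
    dt = segment.amp.grid_dt
    n = segment.amp.n
    if n * dt < baseline_s + min_dur_s:
        return []
    x = segment_level_values(segment)
    valid = ~segment.amp.quality_mask
    w = max(1, int(round(baseline_s / dt)))
    baseline = _rolling_baseline(x, valid, w)

    events: list[VasoEvent] = []
    i = 1
    while i < n:
        b = baseline[i]
        if (not valid[i]) or not np.isfinite(b) or b <= 0 \
                or x[i] >= b * (1.0 - depth_thresh):
            i += 1
            continue
        onset = i
        flags: list[str] = []
        if onset < w:
            flags.append("short_baseline")
        j = onset
        while j < n and valid[j] and x[j] < b:
            j += 1
        if j >= n:
            flags.append("truncated")
        elif not valid[j]:
            flags.append("masked")
        lo = onset - 1
        hi = min(j, n - 1)
        drop = np.clip(b - x[lo:hi + 1], 0.0, None)
        drop[~valid[lo:hi + 1]] = 0.0
        area = float(np.trapezoid(drop, dx=dt))
        duration = (j - onset) * dt
        if duration >= min_dur_s:
            events.append(VasoEvent(
                start=segment.t_start + onset * dt,
                end=segment.t_start + j * dt,
                baseline=float(b),
                drop_area=area,
                mvasoc=mvasoc_of_event(area, duration, float(b)),
                flags=flags,
            ))
        i = j + 1
    return events


def ppgamp_cv(series: AmpSeries, window_s: float = 300.0,
              step_s: float = 30.0,
              max_masked_frac: float = 0.25) -> CVSeries:
    """Sliding-window coefficient of variation of PPGamp.

    One value per ``step_s`` at every center where the full window fits.
    SD is the sample standard deviation (ddof=1) over unmasked in-window
    points; a point is invalid if more than 25% of its window is masked or
    the window mean is nonpositive.
    """
    if series.duration < window_s:
        raise InsufficientDataError(
            f"series of {series.duration:.0f} s shorter than window {window_s:.0f} s")
    dt = series.grid_dt
    half = window_s / 2.0
    first = series.t0 + half
    last = series.t0 + series.duration - half
    n_steps = int(np.floor((last - first) / step_s)) + 1
    centers = first + np.arange(n_steps) * step_s

    x = series.values
    valid = ~series.quality_mask
    xv = np.where(valid, x, 0.0)
    cs = np.concatenate([[0.0], np.cumsum(xv)])
    cs2 = np.concatenate([[0.0], np.cumsum(xv * xv)])
    cn = np.concatenate([[0], np.cumsum(valid.astype(np.int64))])

    w_pts = int(round(window_s / dt))
    lo = np.rint((centers - half - series.t0) / dt).astype(np.int64)
    lo = np.clip(lo, 0, series.n)
    hi = np.clip(lo + w_pts, 0, series.n)
    cnt = cn[hi] - cn[lo]
    total = hi - lo
    s1 = cs[hi] - cs[lo]
    s2 = cs2[hi] - cs2[lo]

    values = np.full(n_steps, np.nan)
    mask_ok = (total - cnt) <= max_masked_frac * np.maximum(total, 1)
    ok = (cnt >= 2) & mask_ok
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > 0, s1 / np.maximum(cnt, 1), np.nan)
        var = np.where(cnt > 1,
                       (s2 - np.maximum(cnt, 1) * mean ** 2)
                       / np.maximum(cnt - 1, 1), np.nan)
    var = np.clip(var, 0.0, None)
    ok &= np.isfinite(mean) & (mean > 0)
    values[ok] = np.sqrt(var[ok]) / mean[ok]
    return CVSeries(window_s=window_s, step_s=step_s, centers=centers,
                    values=values, valid_mask=ok)


def assemble_night_series(segments: list[Segment]) -> AmpSeries:
    """Stitch cleaned segments back into one night-long AmpSeries.

    Values are the level re-offset clean signal; points in non-viable
    segments are masked.
    """
    if not segments:
        raise InsufficientDataError("no segments to assemble")
    dt = segments[0].amp.grid_dt
    t0 = segments[0].t_start
    n_total = sum(s.amp.n for s in segments)
    values = np.zeros(n_total)
    mask = np.ones(n_total, dtype=bool)
    pos = 0
    for seg in segments:
        k = seg.amp.n
        if seg.viable:
            values[pos:pos + k] = segment_level_values(seg)
            mask[pos:pos + k] = seg.amp.quality_mask
        pos += k
    return AmpSeries(grid_dt=dt, values=values, quality_mask=mask,
                     stage_tag=segments[0].amp.stage_tag
                     if segments[0].viable else "raw", t0=t0)


def summarize_night(events_by_segment: dict[int, list[VasoEvent]],
                    cv: CVSeries | None, *, night_id: str = "",
                    device_id: str = "",
                    n_viable_segments: int = 0) -> NightSummary:
    """Nightly medians of both markers plus event counts.

    ``median_mvasoc`` is the median over all event values across viable
    segments; NaN (missing, night retained) when no events were detected.
    """
    mv = [e.mvasoc for evs in events_by_segment.values() for e in evs]
    median_mv = float(np.median(mv)) if mv else float("nan")
    if cv is not None and bool(np.any(cv.valid_mask)):
        median_cv = float(np.median(cv.values[cv.valid_mask]))
    else:
        median_cv = float("nan")
    return NightSummary(night_id=night_id, device_id=device_id,
                        n_events=len(mv), median_mvasoc=median_mv,
                        median_cv=median_cv,
                        n_viable_segments=n_viable_segments)
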