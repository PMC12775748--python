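"""Correlation surfaces validating the markers within and across devices.

* within-device: Mvasoc paired with PPGampCV on the CV grid, per 15-minute
  segment and pooled over the whole night ("overnight" r) with the best
  segment reported as "peak" r;
* across-device: PPGampCV of finger vs wrist on aligned segments, where a
  segment pair is included only if both devices detected at least 3
  vasoconstriction events in it;
* cohort level: ordinary least squares of nightly median Mvasoc on nightly
  median PPGampCV.

Pearson correlation is the default estimator (Spearman available); p-values
are two-sided from the t distribution with n-2 degrees of freedom. No
multiple-testing correction is applied, matching per-night reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from vasowave.errors import ConfigurationError, InsufficientDataError
from vasowave.alignment import PairAlignment
from vasowave.preprocess import Segment
from vasowave.vasomarkers import CVSeries, NightSummary, VasoEvent, ppgamp_cv

__all__ = ["SegmentCorr", "CorrReport", "pearson_with_p",
           "pair_mvasoc_with_cv", "within_device_report",
           "across_device_report", "nightly_medians_regression"]

MIN_PAIRS_PER_SEGMENT = 10


@dataclass
class SegmentCorr:
    index: int
    r: float
    p: float
    n_pairs: int
    included: bool
    exclusion_reason: str  # "" | too_few_events | not_viable | alignment_failed | too_few_pairs


@dataclass
class CorrReport:
    """Per-night correlation report (within- or across-device)."""

    mode: str  # "within_device" | "across_device"
    overnight_r: float
    overnight_p: float
    peak_r: float
    peak_segment: int  # -1 when no segment was included
    per_segment: list[SegmentCorr] = field(default_factory=list)

    @property
    def n_included(self) -> int:
        return sum(1 for s in self.per_segment if s.included)


def pearson_with_p(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation coefficient with a two-sided p-value.

    Pearson by default (t distribution, n-2 df); ``method="spearman"``
    switches the estimator. Requires n >= 3 and non-constant inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ConfigurationError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"need n >= 3 samples, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InsufficientDataError("correlation undefined for constant input")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ConfigurationError(f"unknown correlation method {method!r}")
    return float(res.statistic), float(res.pvalue)


def pair_mvasoc_with_cv(events: list[VasoEvent], cv: CVSeries,
                        mode: str = "zero_fill"
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample the event series onto the CV grid and pair the two channels.

    Each event's mvasoc is held constant over its interval; outside events
    the channel is zero (``zero_fill``) or excluded (``event_only``).
    Returns ``(mvasoc_values, cv_values, grid_indices)`` over the points
    valid in both channels.
    """
    if mode not in ("zero_fill", "event_only"):
        raise ConfigurationError(f"unknown pairing mode {mode!r}")
    mv = np.zeros(cv.n)
    covered = np.zeros(cv.n, dtype=bool)
    for ev in events:
        sel = (cv.centers >= ev.start) & (cv.centers < ev.end)
        mv[sel] = ev.mvasoc
        covered[sel] = True
    keep = cv.valid_mask.copy()
    if mode == "event_only":
        keep &= covered
    idx = np.nonzero(keep)[0]
    return mv[idx], cv.values[idx], idx


def _pooled(pairs_a: list[np.ndarray], pairs_b: list[np.ndarray],
            method: str) -> tuple[float, float]:
    if not pairs_a:
        return float("nan"), float("nan")
    a = np.concatenate(pairs_a)
    b = np.concatenate(pairs_b)
    try:
        return pearson_with_p(a, b, method)
    except InsufficientDataError:
        return float("nan"), float("nan")


def _finish(mode: str, rows: list[SegmentCorr], pooled_a, pooled_b,
            method: str) -> CorrReport:
    overnight_r, overnight_p = _pooled(pooled_a, pooled_b, method)
    included = [s for s in rows if s.included]
    if included:
        best = max(included, key=lambda s: s.r)
        peak_r, peak_segment = best.r, best.index
    else:
        peak_r, peak_segment = float("nan"), -1
    return CorrReport(mode=mode, overnight_r=overnight_r,
                      overnight_p=overnight_p, peak_r=peak_r,
                      peak_segment=peak_segment, per_segment=rows)


def within_device_report(segments: list[Segment],
                         events_by_segment: dict[int, list[VasoEvent]],
                         cv: CVSeries, *, pairing_mode: str = "zero_fill",
                         min_pairs: int = MIN_PAIRS_PER_SEGMENT,
                         method: str = "pearson") -> CorrReport:
    """Correlate Mvasoc with PPGampCV per segment and over the whole night.

    The overnight coefficient pools the paired points of every included
    segment; the peak is the maximum per-segment coefficient among
    segments with at least ``min_pairs`` pairs.
    """
    rows: list[SegmentCorr] = []
    pooled_a: list[np.ndarray] = []
    pooled_b: list[np.ndarray] = []
    for seg in segments:
        if not seg.viable:
            rows.append(SegmentCorr(seg.index, float("nan"), float("nan"),
                                    0, False, "not_viable"))
            continue
        in_seg = (cv.centers >= seg.t_start) & (cv.centers < seg.t_end)
        sub = CVSeries(cv.window_s, cv.step_s, cv.centers[in_seg],
                       cv.values[in_seg], cv.valid_mask[in_seg])
        events = events_by_segment.get(seg.index, [])
        mv, cvv, _ = pair_mvasoc_with_cv(events, sub, pairing_mode)
        n_pairs = mv.size
        if n_pairs < min_pairs:
            rows.append(SegmentCorr(seg.index, float("nan"), float("nan"),
                                    int(n_pairs), False, "too_few_pairs"))
            continue
        if np.ptp(mv) == 0:
            # constant event channel (typically: no events in the segment)
            rows.append(SegmentCorr(seg.index, float("nan"), float("nan"),
                                    int(n_pairs), False, "too_few_events"))
            continue
        try:
            r, p = pearson_with_p(mv, cvv, method)
        except InsufficientDataError:
            rows.append(SegmentCorr(seg.index, float("nan"), float("nan"),
                                    int(n_pairs), False, "too_few_pairs"))
            continue
        rows.append(SegmentCorr(seg.index, r, p, int(n_pairs), True, ""))
        pooled_a.append(mv)
        pooled_b.append(cvv)
    return _finish("within_device", rows, pooled_a, pooled_b, method)


def across_device_report(alignments: list[PairAlignment],
                         finger_events: dict[int, list[VasoEvent]],
                         wrist_events: dict[int, list[VasoEvent]], *,
                         min_events: int = 3,
                         min_pairs: int = MIN_PAIRS_PER_SEGMENT,
                         window_s: float = 300.0, step_s: float = 30.0,
                         method: str = "pearson") -> CorrReport:
    """Correlate PPGampCV across devices on aligned segment pairs.

    A pair is included only if alignment succeeded and BOTH devices
    detected at least ``min_events`` vasoconstriction events in the
    segment. CV is recomputed on the aligned overlapping support so both
    channels share one center grid.
    """
    rows: list[SegmentCorr] = []
    pooled_a: list[np.ndarray] = []
    pooled_b: list[np.ndarray] = []
    for pair in alignments:
        idx = pair.index
        if pair.failure is not None:
            rows.append(SegmentCorr(idx, float("nan"), float("nan"), 0,
                                    False, pair.failure))
            continue
        n_f = len(finger_events.get(idx, []))
        n_w = len(wrist_events.get(idx, []))
        if n_f < min_events or n_w < min_events:
            rows.append(SegmentCorr(idx, float("nan"), float("nan"), 0,
                                    False, "too_few_events"))
            continue
        try:
            cv_f = ppgamp_cv(pair.finger, window_s, step_s)
            cv_w = ppgamp_cv(pair.wrist, window_s, step_s)
        except InsufficientDataError:
            rows.append(SegmentCorr(idx, float("nan"), float("nan"), 0,
                                    False, "too_few_pairs"))
            continue
        both = cv_f.valid_mask & cv_w.valid_mask
        a, b = cv_f.values[both], cv_w.values[both]
        if a.size < min_pairs:
            rows.append(SegmentCorr(idx, float("nan"), float("nan"),
                                    int(a.size), False, "too_few_pairs"))
            continue
        try:
            r, p = pearson_with_p(a, b, method)
        except InsufficientDataError:
            rows.append(SegmentCorr(idx, float("nan"), float("nan"),
                                    int(a.size), False, "too_few_pairs"))
            continue
        rows.append(SegmentCorr(idx, r, p, int(a.size), True, ""))
        pooled_a.append(a)
        pooled_b.append(b)
    return _finish("across_device", rows, pooled_a, pooled_b, method)


def nightly_medians_regression(summaries: list[NightSummary]
                               ) -> tuple[float, float, float]:
    """OLS of nightly median Mvasoc on nightly median PPGampCV.

    Returns ``(slope, intercept, r_squared)``. Nights with an undefined
    median (no events / no valid CV) are dropped first.
    """
    xs = [s.median_cv for s in summaries
          if np.isfinite(s.median_cv) and np.isfinite(s.median_mvasoc)]
    ys = [s.median_mvasoc for s in summaries
          if np.isfinite(s.median_cv) and np.isfinite(s.median_mvasoc)]
    if len(xs) < 3:
        raise InsufficientDataError(
            f"need >= 3 nights with defined medians, got {len(xs)}")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(x) == 0:
        raise InsufficientDataError("zero variance in predictor medians")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)
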