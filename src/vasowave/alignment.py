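"""Cross-device synchronisation of PPGamp segments.

Corresponding finger and wrist segments sit on independent time bases. Each
pair is aligned by sliding one over the other and picking the lag of maximum
positive normalized cross-correlation within a ±30 s window; before that,
each series must pass an autocorrelation check ruling out pure noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from vasowave.errors import AlignmentError, ConfigurationError, InsufficientDataError
from vasowave.pulse_extraction import AmpSeries, _interp_over_mask
from vasowave.preprocess import Segment

__all__ = ["AlignmentResult", "AutocorrResult", "PairAlignment",
           "autocorr_check", "align_pair", "align_night"]

_MIN_OVERLAP_PTS = 10


class AutocorrResult(NamedTuple):
    statistic: float  # max |autocorrelation| over the tested lags
    passed: bool
    reason: str  # "" | "degenerate" | "below_band"


@dataclass
class AlignmentResult:
    """Outcome of one pairwise lag search."""

    lag_s: float  # wrist shift relative to finger; negative = wrist leads
    peak_xcorr: float
    passed_autocheck: tuple[bool, bool]
    boundary_flag: bool  # |lag| hit the search-window edge


@dataclass
class PairAlignment:
    """Per-segment alignment bookkeeping for one night."""

    index: int
    result: AlignmentResult | None
    finger: AmpSeries | None  # overlapping support after the shift
    wrist: AmpSeries | None
    failure: str | None  # None | not_viable | alignment_failed


def autocorr_check(series: AmpSeries, max_lag_s: float = 30.0
                   ) -> AutocorrResult:
    """Check that a series is serially correlated rather than white noise.

    Tests autocorrelations at all grid lags in ``(0, max_lag_s]`` against
    the white-noise 95% band (±1.96/sqrt(N), Bonferroni-adjusted for the
    number of lags tested). A constant series fails with reason
    ``degenerate``.
    """
    dt = series.grid_dt
    n_lags = int(round(max_lag_s / dt))
    if n_lags < 1:
        raise ConfigurationError("max_lag_s shorter than one grid step")
    valid = ~series.quality_mask
    n = int(np.count_nonzero(valid))
    if n < 2 * n_lags:
        raise InsufficientDataError(
            f"need >= {2 * n_lags} valid points, got {n}")
    x = _interp_over_mask(series.values, series.quality_mask)
    x = x - np.mean(x)
    denom = float(np.dot(x, x))
    if denom <= 0:
        return AutocorrResult(0.0, False, "degenerate")
    stat = 0.0
    for k in range(1, n_lags + 1):
        r = float(np.dot(x[:-k], x[k:]) / denom)
        stat = max(stat, abs(r))
    band = stats.norm.ppf(1.0 - 0.025 / n_lags) / np.sqrt(n)
    passed = stat > band
    return AutocorrResult(stat, passed, "" if passed else "below_band")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt(np.dot(a, a) * np.dot(b, b))
    if denom <= 0:
        return np.nan
    return float(np.dot(a, b) / denom)


def align_pair(finger_seg: Segment, wrist_seg: Segment,
               max_lag_s: float = 30.0
               ) -> tuple[AlignmentResult, AmpSeries, AmpSeries]:
    """Find the lag of maximum positive cross-correlation within ±max_lag_s.

    The correlation at each grid lag is the Pearson coefficient between the
    overlapping valid points (scale-free, so the "maximum positive"
    criterion is meaningful). Ties break toward the smallest ``|lag|``.
    Returns the result plus the finger and wrist series restricted to the
    overlapping support after shifting the wrist by ``-lag``.

    Raises :class:`AlignmentError` when no lag yields positive correlation.
    """
    fa, wa = finger_seg.amp, wrist_seg.amp
    if abs(fa.grid_dt - wa.grid_dt) > 1e-12:
        raise ConfigurationError("segments must share one grid_dt")
    if not (finger_seg.viable and wrist_seg.viable):
        raise ConfigurationError("both segments must be viable")
    dt = fa.grid_dt
    k_max = int(round(max_lag_s / dt))

    checks = (autocorr_check(fa, max_lag_s), autocorr_check(wa, max_lag_s))
    passed = (checks[0].passed, checks[1].passed)

    x, xm = fa.values, ~fa.quality_mask
    y, ym = wa.values, ~wa.quality_mask
    n_x, n_y = x.size, y.size

    best_k: int | None = None
    best_r = -np.inf
    for k in sorted(range(-k_max, k_max + 1), key=abs):
        # pair finger[i] with wrist[i + k]
        i_lo = max(0, -k)
        i_hi = min(n_x, n_y - k)
        if i_hi - i_lo < _MIN_OVERLAP_PTS:
            continue
        sel = xm[i_lo:i_hi] & ym[i_lo + k:i_hi + k]
        if np.count_nonzero(sel) < _MIN_OVERLAP_PTS:
            continue
        r = _pearson(x[i_lo:i_hi][sel], y[i_lo + k:i_hi + k][sel])
        if np.isfinite(r) and r > best_r:
            best_r = r
            best_k = k
    if best_k is None or best_r <= 0:
        raise AlignmentError(
            "no positive cross-correlation within the lag window")

    boundary = abs(best_k) == k_max
    if boundary:
        warnings.warn("alignment lag hit the search-window edge; the true "
                      "lag may lie outside ±%g s" % max_lag_s, stacklevel=2)
    result = AlignmentResult(lag_s=best_k * dt, peak_xcorr=best_r,
                             passed_autocheck=passed, boundary_flag=boundary)

    k = best_k
    i_lo = max(0, -k)
    i_hi = min(n_x, n_y - k)
    finger_out = AmpSeries(grid_dt=dt, values=x[i_lo:i_hi].copy(),
                           quality_mask=fa.quality_mask[i_lo:i_hi].copy(),
                           stage_tag=fa.stage_tag, t0=fa.t0 + i_lo * dt)
    wrist_out = AmpSeries(grid_dt=dt, values=y[i_lo + k:i_hi + k].copy(),
                          quality_mask=wa.quality_mask[i_lo + k:i_hi + k].copy(),
                          stage_tag=wa.stage_tag, t0=fa.t0 + i_lo * dt)
    return result, finger_out, wrist_out


def align_night(finger_segments: list[Segment], wrist_segments: list[Segment],
                max_lag_s: float = 30.0) -> list[PairAlignment]:
    """Align every corresponding segment pair of a night; never raises.

    The returned overlapping series carry the level re-offset clean values
    (positive mean) so sliding-window CV stays meaningful downstream; the
    lag search itself is offset-invariant.
    """
    from vasowave.vasomarkers import segment_level_values

    out: list[PairAlignment] = []
    for f_seg, w_seg in zip(finger_segments, wrist_segments):
        idx = f_seg.index
        if not (f_seg.viable and w_seg.viable):
            out.append(PairAlignment(idx, None, None, None, "not_viable"))
            continue
        f_seg = f_seg.copy()
        f_seg.amp.values = segment_level_values(f_seg)
        w_seg = w_seg.copy()
        w_seg.amp.values = segment_level_values(w_seg)
        try:
            result, f_amp, w_amp = align_pair(f_seg, w_seg, max_lag_s)
        except (AlignmentError, InsufficientDataError):
            out.append(PairAlignment(idx, None, None, None, "alignment_failed"))
            continue
        if not all(result.passed_autocheck):
            out.append(PairAlignment(idx, result, None, None,
                                     "alignment_failed"))
            continue
        out.append(PairAlignment(idx, result, f_amp, w_amp, None))
    return out
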