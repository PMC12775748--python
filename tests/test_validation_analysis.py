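import numpy as np
import pytest

from conftest import make_segment
from vasowave.alignment import PairAlignment, AlignmentResult
from vasowave.errors import ConfigurationError, InsufficientDataError
from vasowave.pulse_extraction import AmpSeries
from vasowave.preprocess import Segment
from vasowave.validation_analysis import (
    across_device_report,
    nightly_medians_regression,
    pair_mvasoc_with_cv,
    pearson_with_p,
    within_device_report,
)
from vasowave.vasomarkers import CVSeries, NightSummary, VasoEvent


def cv_of(values, centers=None, step=30.0, valid=None):
    values = np.asarray(values, dtype=float)
    if centers is None:
        centers = 150.0 + step * np.arange(values.size)
    valid = np.ones(values.size, dtype=bool) if valid is None else valid
    return CVSeries(window_s=300.0, step_s=step, centers=np.asarray(centers),
                    values=values, valid_mask=valid)


class TestPearsonWithP:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, p = pearson_with_p(x, x)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_hand_vectors_formula_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 5.0])
        # independent oracle: product-moment formula by hand
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        expected = sxy / np.sqrt(np.sum((x - x.mean()) ** 2)
                                 * np.sum((y - y.mean()) ** 2))
        assert expected == pytest.approx(0.9827, abs=1e-4)
        r, _ = pearson_with_p(x, y)
        assert r == pytest.approx(expected, rel=1e-12)

    def test_n2_rejected(self):
        with pytest.raises(InsufficientDataError):
            pearson_with_p([1.0, 2.0], [1.0, 2.0])

    def test_constant_rejected(self):
        with pytest.raises(InsufficientDataError):
            pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_spearman_mode(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, _ = pearson_with_p(x, x ** 3, method="spearman")
        assert r == pytest.approx(1.0)

    def test_unknown_method(self):
        with pytest.raises(ConfigurationError):
            pearson_with_p([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], method="kendall")


class TestPairMvasocWithCv:
    def test_single_event_covers_grid(self):
        cv = cv_of(np.linspace(0.1, 0.2, 10))
        events = [VasoEvent(0.0, 1000.0, 1.0, 100.0, 0.33)]
        mv, cvv, idx = pair_mvasoc_with_cv(events, cv)
        assert mv.size == 10
        assert np.all(mv == 0.33)
        np.testing.assert_array_equal(cvv, cv.values)

    def test_no_events_zero_fill_retained(self):
        cv = cv_of(np.linspace(0.1, 0.2, 10))
        mv, cvv, idx = pair_mvasoc_with_cv([], cv, mode="zero_fill")
        assert mv.size == 10
        assert np.all(mv == 0.0)

    def test_event_only_mode_restricts(self):
        cv = cv_of(np.linspace(0.1, 0.2, 10))
        events = [VasoEvent(150.0, 230.0, 1.0, 10.0, 0.5)]  # covers 3 centers
        mv, cvv, idx = pair_mvasoc_with_cv(events, cv, mode="event_only")
        assert mv.size == 3
        assert np.all(mv == 0.5)

    def test_pair_count_bookkeeping(self):
        valid = np.array([True] * 6 + [False] * 4)
        cv = cv_of(np.linspace(0.1, 0.2, 10), valid=valid)
        mv, cvv, idx = pair_mvasoc_with_cv([], cv)
        assert mv.size == int(valid.sum())
        np.testing.assert_array_equal(idx, np.flatnonzero(valid))


def night_with_events(values, n_events=12, seg_len=900.0):
    """One viable segment + events laid out so the mv channel tracks values."""
    seg = make_segment(np.ones(int(seg_len / 0.5)))
    centers = 150.0 + 30.0 * np.arange(len(values))
    events = [VasoEvent(c - 10.0, c + 10.0, 1.0, v * 20.0, v)
              for c, v in zip(centers, values)]
    cv = cv_of(np.asarray(values), centers=centers)
    return seg, events, cv


class TestWithinDeviceReport:
    def test_identical_channels_r_one(self):
        values = np.linspace(0.1, 0.5, 20)
        seg, events, cv = night_with_events(values)
        report = within_device_report([seg], {0: events}, cv)
        assert report.per_segment[0].included
        assert report.per_segment[0].r == pytest.approx(1.0)
        assert report.overnight_r == pytest.approx(1.0)
        assert report.peak_r == pytest.approx(1.0)
        assert report.peak_segment == 0

    def test_negated_channel_r_minus_one(self):
        values = np.linspace(0.1, 0.5, 20)
        seg, events, cv = night_with_events(values)
        cv_neg = cv_of(-np.asarray(values), centers=cv.centers)
        report = within_device_report([seg], {0: events}, cv_neg)
        assert report.overnight_r == pytest.approx(-1.0)

    def test_no_events_excluded(self):
        seg = make_segment(np.ones(1800))
        cv = cv_of(np.linspace(0.1, 0.2, 20))
        report = within_device_report([seg], {0: []}, cv)
        assert not report.per_segment[0].included
        assert report.per_segment[0].exclusion_reason == "too_few_events"

    def test_non_viable_excluded(self):
        seg = make_segment(np.ones(1800), viable=False)
        cv = cv_of(np.linspace(0.1, 0.2, 20))
        report = within_device_report([seg], {}, cv)
        assert report.per_segment[0].exclusion_reason == "not_viable"
        assert report.peak_segment == -1

    def test_peak_is_max_over_included(self):
        v1 = np.linspace(0.1, 0.5, 20)
        rng = np.random.default_rng(0)
        v2 = np.linspace(0.1, 0.5, 20) + 0.3 * rng.normal(size=20) * 0.1
        seg1, ev1, cv1 = night_with_events(v1)
        seg2, ev2, cv2 = night_with_events(v2)
        seg2.index = 1
        seg2.t_start += 900.0
        seg2.t_end += 900.0
        ev2 = [VasoEvent(e.start + 900, e.end + 900, e.baseline, e.drop_area,
                         e.mvasoc) for e in ev2]
        cv = cv_of(np.concatenate([v1, v2]),
                   centers=np.concatenate([cv1.centers, cv2.centers + 900.0]))
        report = within_device_report([seg1, seg2], {0: ev1, 1: ev2}, cv)
        rs = [s.r for s in report.per_segment if s.included]
        assert report.peak_r == pytest.approx(max(rs))


def aligned_pair(index, f_values, w_values, grid_dt=0.5):
    n = f_values.size
    f = AmpSeries(grid_dt=grid_dt, values=f_values, stage_tag="raw")
    w = AmpSeries(grid_dt=grid_dt, values=w_values, stage_tag="raw")
    res = AlignmentResult(lag_s=0.0, peak_xcorr=0.9,
                          passed_autocheck=(True, True), boundary_flag=False)
    return PairAlignment(index, res, f, w, None)


class TestAcrossDeviceReport:
    def drive(self, seed=0, n=1800):
        rng = np.random.default_rng(seed)
        t = np.arange(n) * 0.5
        return (1 + 0.3 * np.sin(2 * np.pi * 0.008 * t)
                + 0.1 * np.sin(2 * np.pi * 0.02 * t)
                + 0.02 * rng.normal(size=n))

    def events(self, k):
        return [VasoEvent(10.0 * i, 10.0 * i + 5, 1.0, 1.0, 0.2)
                for i in range(k)]

    def test_min_events_rule(self):
        # 2 finger events vs 5 wrist events -> excluded
        x = self.drive()
        pair = aligned_pair(0, x, x)
        report = across_device_report([pair], {0: self.events(2)},
                                      {0: self.events(5)}, min_events=3)
        assert not report.per_segment[0].included
        assert report.per_segment[0].exclusion_reason == "too_few_events"

    def test_identical_series_r_one(self):
        x = self.drive()
        pair = aligned_pair(0, x, x.copy())
        report = across_device_report([pair], {0: self.events(5)},
                                      {0: self.events(5)})
        assert report.per_segment[0].included
        assert report.overnight_r == pytest.approx(1.0)

    def test_alignment_failure_reason_propagates(self):
        pair = PairAlignment(0, None, None, None, "alignment_failed")
        report = across_device_report([pair], {0: self.events(5)},
                                      {0: self.events(5)})
        assert report.per_segment[0].exclusion_reason == "alignment_failed"

    def test_exclusion_does_not_change_included_r(self):
        x1, x2 = self.drive(1), self.drive(2)
        pairs = [aligned_pair(0, x1, x1 * 1.1), aligned_pair(1, x2, x2 * 0.9)]
        ev = {0: self.events(5), 1: self.events(2)}
        full = across_device_report(pairs, {0: self.events(5), 1: self.events(5)},
                                    {0: self.events(5), 1: self.events(5)})
        partial = across_device_report(pairs, ev, ev)
        r_full = {s.index: s.r for s in full.per_segment if s.included}
        r_partial = {s.index: s.r for s in partial.per_segment if s.included}
        assert set(r_partial) == {0}
        assert r_partial[0] == r_full[0]

    def test_min_events_monotone_inclusion(self):
        x1, x2 = self.drive(3), self.drive(4)
        pairs = [aligned_pair(0, x1, x1), aligned_pair(1, x2, x2)]
        ev = {0: self.events(5), 1: self.events(2)}
        counts = []
        for m in (0, 3, 6):
            rep = across_device_report(pairs, ev, ev, min_events=m)
            counts.append(rep.n_included)
        assert counts == sorted(counts, reverse=True)


class TestNightlyMediansRegression:
    def summaries(self, xs, ys):
        return [NightSummary(str(i), "wrist", 5, y, x, 4)
                for i, (x, y) in enumerate(zip(xs, ys))]

    def test_collinear_r2_one(self):
        s = self.summaries([0.1, 0.2, 0.3, 0.4], [1.0, 2.0, 3.0, 4.0])
        slope, intercept, r2 = nightly_medians_regression(s)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(10.0)

    def test_hand_data_least_squares_oracle(self):
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([0.0, 1.0, 2.1])
        # independent least-squares oracle
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        syy = np.sum((y - y.mean()) ** 2)
        exp_slope = sxy / sxx
        exp_r2 = sxy ** 2 / (sxx * syy)
        slope, intercept, r2 = nightly_medians_regression(self.summaries(x, y))
        assert slope == pytest.approx(exp_slope, rel=1e-12)
        assert r2 == pytest.approx(exp_r2, rel=1e-12)
        assert r2 == pytest.approx(0.99924, abs=1e-5)

    def test_too_few_nights(self):
        with pytest.raises(InsufficientDataError):
            nightly_medians_regression(self.summaries([0.1, 0.2], [1.0, 2.0]))

    def test_zero_variance_predictor(self):
        with pytest.raises(InsufficientDataError):
            nightly_medians_regression(
                self.summaries([0.2, 0.2, 0.2], [1.0, 2.0, 3.0]))

    def test_nan_nights_dropped(self):
        s = self.summaries([0.1, 0.2, 0.3, 0.4], [1.0, 2.0, 3.0, 4.0])
        s.append(NightSummary("x", "wrist", 0, float("nan"), 0.5, 4))
        slope, _, r2 = nightly_medians_regression(s)
        assert r2 == pytest.approx(1.0)
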