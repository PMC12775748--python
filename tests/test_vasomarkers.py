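import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_segment, make_series
from vasowave.errors import ConfigurationError, InsufficientDataError
from vasowave.config import RunConfig
from vasowave.pipeline import process_night
from vasowave.synthetic_data import SimConfig, simulate_night
from vasowave.vasomarkers import (
    detect_vaso_events,
    mvasoc_of_event,
    ppgamp_cv,
    summarize_night,
)


def dip_segment(baseline=1.0, depth=0.5, start=60.0, dur=10.0, total=300.0,
                grid_dt=0.5, shape="rect"):
    t = np.arange(0, total, grid_dt)
    x = np.full(t.size, baseline)
    inside = (t >= start) & (t < start + dur)
    if shape == "rect":
        x[inside] -= depth * baseline
    else:  # triangle
        rel = (t[inside] - start) / dur
        x[inside] -= depth * baseline * (1 - np.abs(2 * rel - 1))
    return make_segment(x, grid_dt=grid_dt)


class TestMvasocOfEvent:
    def test_direct_formula(self):
        assert mvasoc_of_event(5.0, 10.0, 1.0) == 0.5

    def test_zero_area(self):
        assert mvasoc_of_event(0.0, 10.0, 1.0) == 0.0

    @pytest.mark.parametrize("area,dur,base", [
        (5.0, 0.0, 1.0), (5.0, 10.0, 0.0), (-1.0, 10.0, 1.0)])
    def test_domain_errors(self, area, dur, base):
        with pytest.raises(ConfigurationError):
            mvasoc_of_event(area, dur, base)


class TestDetectVasoEvents:
    def test_constant_segment_no_events(self):
        assert detect_vaso_events(make_segment(np.ones(1800))) == []

    def test_rectangular_dip_closed_form(self):
        # (d*b*T / T) / b = d
        seg = dip_segment(baseline=1.0, depth=0.5, dur=10.0)
        events = detect_vaso_events(seg, depth_thresh=0.2, min_dur_s=2.0)
        assert len(events) == 1
        ev = events[0]
        assert ev.duration == pytest.approx(10.0, rel=0.05)
        assert ev.mvasoc == pytest.approx(0.5, rel=0.05)
        assert ev.baseline == pytest.approx(1.0, rel=1e-6)

    def test_rect_dip_scale_invariance(self):
        e1 = detect_vaso_events(dip_segment(baseline=1.0), depth_thresh=0.2)[0]
        e2 = detect_vaso_events(dip_segment(baseline=5.0), depth_thresh=0.2)[0]
        assert e2.mvasoc == pytest.approx(e1.mvasoc, rel=1e-9)
        assert e2.baseline == pytest.approx(5 * e1.baseline, rel=1e-9)
        assert e2.drop_area == pytest.approx(5 * e1.drop_area, rel=1e-9)

    def test_triangular_dip_closed_form(self):
        # area d*T/2 => mvasoc -> d/2 as the onset threshold vanishes
        seg = dip_segment(depth=0.4, dur=40.0, shape="triangle")
        events = detect_vaso_events(seg, depth_thresh=0.02, min_dur_s=2.0)
        assert len(events) == 1
        assert events[0].mvasoc == pytest.approx(0.2, rel=0.05)

    def test_two_dips_independent_baselines(self):
        grid_dt = 0.5
        t = np.arange(0, 600, grid_dt)
        x = np.ones(t.size)
        x[(t >= 100) & (t < 110)] = 0.5
        x[(t >= 200) & (t < 215)] = 0.6
        seg = make_segment(x, grid_dt=grid_dt)
        events = detect_vaso_events(seg, depth_thresh=0.2, min_dur_s=2.0)
        # brute-force reference scan with a frozen baseline of 1.0
        assert len(events) == 2
        assert events[0].start == pytest.approx(100.0, abs=grid_dt)
        assert events[0].end == pytest.approx(110.0, abs=grid_dt)
        assert events[0].mvasoc == pytest.approx(0.5, rel=0.06)
        assert events[1].start == pytest.approx(200.0, abs=grid_dt)
        assert events[1].mvasoc == pytest.approx(0.4, rel=0.06)
        for ev in events:
            assert ev.baseline == pytest.approx(1.0, rel=1e-6)

    def test_short_events_discarded(self):
        seg = dip_segment(dur=2.0)
        assert detect_vaso_events(seg, depth_thresh=0.2, min_dur_s=3.0) == []

    def test_segment_too_short_for_baseline(self):
        seg = make_segment(np.ones(20), grid_dt=0.5)  # 10 s < 15 + 3
        assert detect_vaso_events(seg) == []

    def test_non_viable_segment_skipped(self):
        seg = dip_segment()
        seg.viable = False
        assert detect_vaso_events(seg, depth_thresh=0.2) == []

    def test_truncated_at_boundary_flagged(self):
        t = np.arange(0, 300, 0.5)
        x = np.ones(t.size)
        x[t >= 280] = 0.5  # never recovers
        events = detect_vaso_events(make_segment(x), depth_thresh=0.2,
                                    min_dur_s=2.0)
        assert len(events) == 1
        assert "truncated" in events[0].flags
        assert events[0].end == pytest.approx(300.0, abs=0.5)


class TestPpgampCv:
    def test_constant_series_zero(self):
        series = make_series(np.full(1200, 2.0), grid_dt=0.5)
        cv = ppgamp_cv(series)
        assert cv.valid_mask.all()
        assert np.all(cv.values[cv.valid_mask] == 0.0)

    def test_two_point_window_hand_oracle(self):
        # hand oracle: sample SD of {1,3} = sqrt(2), mean 2 -> CV = 0.7071
        series = make_series(np.array([1.0, 3.0, 1.0, 3.0]), grid_dt=150.0)
        cv = ppgamp_cv(series, window_s=300.0, step_s=30.0)
        expected = np.std([1.0, 3.0], ddof=1) / np.mean([1.0, 3.0])
        assert expected == pytest.approx(0.7071, abs=1e-4)
        assert cv.valid_mask.any()
        np.testing.assert_allclose(cv.values[cv.valid_mask], expected,
                                   rtol=1e-12)

    def test_centers_spacing_and_window_fit(self):
        series = make_series(np.random.default_rng(0).uniform(1, 2, 1800),
                             grid_dt=0.5)  # 900 s
        cv = ppgamp_cv(series, window_s=300.0, step_s=30.0)
        assert np.allclose(np.diff(cv.centers), 30.0)
        assert cv.centers[0] == pytest.approx(150.0)
        assert cv.centers[-1] <= 900.0 - 150.0

    def test_masked_window_invalid(self):
        values = np.random.default_rng(1).uniform(1, 2, 1800)
        mask = np.zeros(1800, dtype=bool)
        mask[:300] = True  # first 150 s fully masked
        cv = ppgamp_cv(make_series(values, grid_dt=0.5, mask=mask))
        assert not cv.valid_mask[0]  # window 0-300 s is 50% masked

    def test_nonpositive_mean_invalid(self):
        values = np.full(1200, -1.0)
        cv = ppgamp_cv(make_series(values, grid_dt=0.5))
        assert not cv.valid_mask.any()

    def test_too_short_series(self):
        with pytest.raises(InsufficientDataError):
            ppgamp_cv(make_series(np.ones(100), grid_dt=0.5))


@settings(max_examples=30, deadline=None)
@given(k=st.floats(min_value=1e-6, max_value=1e6,
                   allow_nan=False, allow_infinity=False))
def test_cv_scale_invariance(k):
    rng = np.random.default_rng(9)
    values = rng.uniform(0.5, 1.5, 1200)
    a = ppgamp_cv(make_series(values, grid_dt=0.5))
    b = ppgamp_cv(make_series(k * values, grid_dt=0.5))
    np.testing.assert_allclose(b.values[b.valid_mask], a.values[a.valid_mask],
                               atol=1e-12, rtol=1e-9)


class TestSummarizeNight:
    def events_with(self, mvasocs):
        from vasowave.vasomarkers import VasoEvent

        return {0: [VasoEvent(10.0 * i, 10.0 * i + 5, 1.0, m * 5, m)
                    for i, m in enumerate(mvasocs)]}

    def test_median_of_three(self):
        s = summarize_night(self.events_with([0.1, 0.2, 0.3]), None)
        assert s.median_mvasoc == pytest.approx(0.2)
        assert s.n_events == 3

    def test_single_event(self):
        s = summarize_night(self.events_with([0.42]), None)
        assert s.median_mvasoc == pytest.approx(0.42)

    def test_no_events_missing_but_retained(self):
        s = summarize_night({}, None, night_id="n", device_id="wrist")
        assert s.n_events == 0
        assert np.isnan(s.median_mvasoc)
        assert s.night_id == "n"

    def test_medians_ordered_by_simulated_intensity(self):
        rc = RunConfig()
        medians_mv, medians_cv = [], []
        for level in range(5):
            mv_all, cv_all = [], []
            for seed in range(3):
                cfg = SimConfig(duration_s=1800.0, seed=100 * level + seed,
                                hourly_pause=False,
                                event_rate_per_h=10.0 + 10.0 * level,
                                event_depth_mean=0.2 + 0.12 * level,
                                wrist_sample_rate=25.0)
                _, wrist, _ = simulate_night(cfg)
                res = process_night(wrist, rc)
                mv_all.append(res.summary.median_mvasoc)
                cv_all.append(res.summary.median_cv)
            medians_mv.append(np.nanmean(mv_all))
            medians_cv.append(np.nanmean(cv_all))
        assert all(a < b for a, b in zip(medians_mv, medians_mv[1:]))
        assert all(a < b for a, b in zip(medians_cv, medians_cv[1:]))
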