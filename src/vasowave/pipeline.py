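"""Orchestration: raw record -> markers -> reports, plus (de)serialization.

The on-disk interchange formats are plain CSV so every intermediate stage
can be inspected and re-fed to the CLI:

* archive record:  ``time_s, ppg, masked[, accel]``
* amp series:      ``t_s, value, masked``
* clean night dir: ``clean.csv`` (``t_s, value, masked, segment``; values
  already re-offset to a positive level) + ``segments.csv``
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

import vasowave
from vasowave.alignment import align_night
from vasowave.config import RunConfig
from vasowave.errors import InsufficientDataError, SchemaError
from vasowave.ppg_io import PPGRecord
from vasowave.preprocess import Segment, clean_segment, segment_night
from vasowave.pulse_extraction import AmpSeries, build_amp_series, detect_beats
from vasowave.synthetic_data import GroundTruth, simulate_night, write_fixture
from vasowave.validation_analysis import (
    CorrReport,
    across_device_report,
    nightly_medians_regression,
    within_device_report,
)
from vasowave.vasomarkers import (
    CVSeries,
    NightSummary,
    VasoEvent,
    assemble_night_series,
    detect_vaso_events,
    ppgamp_cv,
    summarize_night,
)


@dataclass
class NightResult:
    """Everything derived from one night of one device."""

    night_id: str
    device_id: str
    segments: list[Segment]
    events_by_segment: dict[int, list[VasoEvent]]
    cv: CVSeries | None
    summary: NightSummary
    clean: AmpSeries | None


def extract_amp_series(record: PPGRecord, cfg: RunConfig) -> AmpSeries:
    """Beat detection followed by uniform-grid interpolation."""
    beats = detect_beats(record, cfg.hr_min_bpm, cfg.hr_max_bpm,
                         cfg.prominence_frac)
    if len(beats) < 2:
        raise InsufficientDataError("fewer than 2 beats detected")
    accel_t = accel_v = None
    if record.accel_magnitude is not None:
        accel_t = record.times() - record.start_time
        accel_v = record.accel_magnitude
    return build_amp_series(beats, cfg.grid_dt, t_end=record.duration,
                            accel_times=accel_t, accel_values=accel_v)


def process_night(record: PPGRecord, cfg: RunConfig, *, night_id: str = "",
                  device_id: str = "") -> NightResult:
    """Full single-device chain: extract, segment, clean, mark, summarize."""
    device_id = device_id or record.device_id
    series = extract_amp_series(record, cfg)
    segments = [clean_segment(s, max_masked_frac=cfg.max_masked_frac,
                              accel_thresh=cfg.accel_thresh,
                              cap_pctl=cfg.cap_pctl, norm_pctl=cfg.norm_pctl,
                              cutoff_hz=cfg.cutoff_hz)
                for s in segment_night(series, cfg.seg_len_s)]
    events = {s.index: detect_vaso_events(s, cfg.baseline_s, cfg.depth_thresh,
                                          cfg.min_dur_s)
              for s in segments if s.viable}
    clean = cv = None
    try:
        clean = assemble_night_series(segments)
        cv = ppgamp_cv(clean, cfg.window_s, cfg.step_s)
    except InsufficientDataError:
        pass
    n_viable = sum(1 for s in segments if s.viable)
    summary = summarize_night(events, cv, night_id=night_id,
                              device_id=device_id,
                              n_viable_segments=n_viable)
    return NightResult(night_id=night_id, device_id=device_id,
                       segments=segments, events_by_segment=events, cv=cv,
                       summary=summary, clean=clean)


# ---------------------------------------------------------------- serialization

def save_record_archive(record: PPGRecord, path) -> None:
    t = np.arange(record.n_samples) / record.sample_rate
    cols = {"time_s": t, "ppg": record.samples,
            "masked": record.gap_mask.astype(int)}
    if record.accel_magnitude is not None:
        cols["accel"] = record.accel_magnitude
    pd.DataFrame(cols).to_csv(path, index=False)


def load_record_archive(path, *, device_id: str = "",
                        night_id: str = "") -> PPGRecord:
    frame = pd.read_csv(path)
    for col in ("time_s", "ppg", "masked"):
        if col not in frame.columns:
            raise SchemaError(f"{path}: archive column {col!r} missing")
    dt = float(np.median(np.diff(frame["time_s"].to_numpy()))) if len(frame) > 1 else 1.0
    return PPGRecord(sample_rate=1.0 / dt,
                     samples=frame["ppg"].to_numpy(dtype=float),
                     gap_mask=frame["masked"].to_numpy(dtype=bool),
                     accel_magnitude=frame["accel"].to_numpy(dtype=float)
                     if "accel" in frame.columns else None,
                     device_id=device_id, night_id=night_id)


def save_amp_series(series: AmpSeries, path) -> None:
    pd.DataFrame({"t_s": series.times(), "value": series.values,
                  "masked": series.quality_mask.astype(int)}
                 ).to_csv(path, index=False)


def load_amp_series(path, stage_tag: str = "raw") -> AmpSeries:
    frame = pd.read_csv(path)
    t = frame["t_s"].to_numpy(dtype=float)
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.5
    return AmpSeries(grid_dt=dt, values=frame["value"].to_numpy(dtype=float),
                     quality_mask=frame["masked"].to_numpy(dtype=bool),
                     stage_tag=stage_tag, t0=float(t[0]) if len(t) else 0.0)


def save_clean_night(segments: list[Segment], out_dir) -> None:
    """Persist cleaned segments (values re-offset to level) to a directory."""
    from vasowave.vasomarkers import segment_level_values

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    parts, seg_rows = [], []
    for seg in segments:
        vals = segment_level_values(seg) if seg.viable else seg.amp.values
        parts.append(pd.DataFrame({
            "t_s": seg.amp.times(), "value": vals,
            "masked": seg.amp.quality_mask.astype(int),
            "segment": seg.index}))
        seg_rows.append({"segment": seg.index, "t_start": seg.t_start,
                         "t_end": seg.t_end, "viable": int(seg.viable),
                         "notes": "|".join(seg.quality_notes)})
    pd.concat(parts, ignore_index=True).to_csv(out_dir / "clean.csv", index=False)
    pd.DataFrame(seg_rows).to_csv(out_dir / "segments.csv", index=False)


def load_clean_night(in_dir) -> list[Segment]:
    in_dir = Path(in_dir)
    data = pd.read_csv(in_dir / "clean.csv")
    meta = pd.read_csv(in_dir / "segments.csv")
    segments = []
    for row in meta.itertuples():
        sub = data[data["segment"] == row.segment]
        t = sub["t_s"].to_numpy(dtype=float)
        dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.5
        amp = AmpSeries(grid_dt=dt, values=sub["value"].to_numpy(dtype=float),
                        quality_mask=sub["masked"].to_numpy(dtype=bool),
                        stage_tag="detrended_filtered", t0=float(row.t_start))
        notes = [] if pd.isna(row.notes) or not row.notes else str(row.notes).split("|")
        segments.append(Segment(index=int(row.segment), t_start=float(row.t_start),
                                t_end=float(row.t_end), amp=amp,
                                viable=bool(row.viable), quality_notes=notes,
                                pre_detrend_mean=0.0))
    return segments


def events_frame(events_by_segment: dict[int, list[VasoEvent]], *,
                 night_id: str = "", device_id: str = "") -> pd.DataFrame:
    rows = []
    for idx in sorted(events_by_segment):
        for ev in events_by_segment[idx]:
            rows.append({"night": night_id, "device": device_id,
                         "segment": idx, "start_s": ev.start, "end_s": ev.end,
                         "duration_s": ev.duration, "baseline": ev.baseline,
                         "drop_area": ev.drop_area, "mvasoc": ev.mvasoc,
                         "flags": "|".join(ev.flags)})
    cols = ["night", "device", "segment", "start_s", "end_s", "duration_s",
            "baseline", "drop_area", "mvasoc", "flags"]
    return pd.DataFrame(rows, columns=cols)


def cv_frame(cv: CVSeries, *, night_id: str = "",
             device_id: str = "") -> pd.DataFrame:
    return pd.DataFrame({"night": night_id, "device": device_id,
                         "center_s": cv.centers, "cv": cv.values,
                         "valid": cv.valid_mask.astype(int)})


def report_row(report: CorrReport, **extra) -> dict:
    row = dict(extra)
    row.update({"overnight_r": report.overnight_r,
                "overnight_p": report.overnight_p,
                "peak_r": report.peak_r, "peak_segment": report.peak_segment,
                "n_segments_included": report.n_included,
                "n_segments_total": len(report.per_segment)})
    return row


# ------------------------------------------------------------------- end-to-end

def run_pipeline(cfg: RunConfig, out_dir) -> dict:
    """Simulate a cohort and run the full analysis, writing a report dir.

    Event intensity is varied deterministically across nights so nightly
    medians span a range. Returns the manifest (also written as JSON).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    summaries: dict[str, list[NightSummary]] = {"finger": [], "wrist": []}
    within_rows, across_rows, nightly_rows = [], [], []
    event_frames, cv_frames = [], []

    for i in range(cfg.n_nights):
        intensity = 0.6 + 1.0 * (i / max(cfg.n_nights - 1, 1))
        sim = cfg.sim_config(i)
        sim.event_rate_per_h = sim.event_rate_per_h * intensity
        sim.event_depth_mean = float(np.clip(
            sim.event_depth_mean * (0.8 + 0.4 * (intensity - 0.6)),
            *sim.event_depth_bounds))
        night_id = f"night{i + 1:02d}"
        finger_rec, wrist_rec, truth = simulate_night(sim)

        results = {}
        for device, rec in (("finger", finger_rec), ("wrist", wrist_rec)):
            res = process_night(rec, cfg, night_id=night_id, device_id=device)
            results[device] = res
            summaries[device].append(res.summary)
            nightly_rows.append({
                "night": night_id, "device": device,
                "n_events": res.summary.n_events,
                "median_mvasoc": res.summary.median_mvasoc,
                "median_cv": res.summary.median_cv,
                "n_viable_segments": res.summary.n_viable_segments})
            if res.cv is not None:
                within = within_device_report(
                    res.segments, res.events_by_segment, res.cv,
                    pairing_mode=cfg.pairing_mode, min_pairs=cfg.min_pairs,
                    method=cfg.correlation)
                within_rows.append(report_row(within, night=night_id,
                                              device=device))
            event_frames.append(events_frame(res.events_by_segment,
                                             night_id=night_id,
                                             device_id=device))
            if res.cv is not None:
                cv_frames.append(cv_frame(res.cv, night_id=night_id,
                                          device_id=device))

        alignments = align_night(results["finger"].segments,
                                 results["wrist"].segments, cfg.max_lag_s)
        across = across_device_report(
            alignments, results["finger"].events_by_segment,
            results["wrist"].events_by_segment, min_events=cfg.min_events,
            min_pairs=cfg.min_pairs, window_s=cfg.window_s,
            step_s=cfg.step_s, method=cfg.correlation)
        lags = [p.result.lag_s for p in alignments if p.result is not None]
        across_rows.append(report_row(
            across, night=night_id,
            median_recovered_lag_s=float(np.median(lags)) if lags else float("nan"),
            true_lag_s=truth.true_lag_s))

    pd.DataFrame(nightly_rows).to_csv(out_dir / "nightly_summary.csv", index=False)
    pd.DataFrame(within_rows).to_csv(out_dir / "within_device.csv", index=False)
    pd.DataFrame(across_rows).to_csv(out_dir / "across_device.csv", index=False)
    pd.concat(event_frames, ignore_index=True).to_csv(
        out_dir / "events.csv", index=False)
    pd.concat(cv_frames, ignore_index=True).to_csv(out_dir / "cv.csv", index=False)

    regression = {}
    for device, rows in summaries.items():
        try:
            slope, intercept, r2 = nightly_medians_regression(rows)
            regression[device] = {"slope": slope, "intercept": intercept,
                                  "r_squared": r2}
        except InsufficientDataError as exc:
            regression[device] = {"error": str(exc)}

    manifest = {
        "package_version": vasowave.__version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "nightly_medians_regression": regression,
        "artifacts": sorted(p.name for p in out_dir.iterdir()
                            if p.suffix == ".csv"),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def simulate_to_dir(cfg: RunConfig, out_dir) -> list[Path]:
    """Write per-night fixtures: finger.edf, wrist.csv, truth.json."""
    out_dir = Path(out_dir)
    paths = []
    for i in range(cfg.n_nights):
        sim = cfg.sim_config(i)
        night_dir = out_dir / f"night{i + 1:02d}"
        night_dir.mkdir(parents=True, exist_ok=True)
        finger, wrist, truth = simulate_night(sim)
        write_fixture(finger, night_dir / "finger.edf", "edf")
        write_fixture(wrist, night_dir / "wrist.csv", "csv")
        truth.to_json(night_dir / "truth.json")
        paths.append(night_dir)
    return paths
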