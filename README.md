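# vasowave

Quantify nocturnal peripheral vasoconstriction from raw photoplethysmography
(PPG). The package extracts the peak-to-trough pulse amplitude (PPGamp) from
wristband CSV exports or finger-sensor EDF recordings and computes two
vasomotor markers:

- **Mvasoc** — per-event magnitude of vasoconstriction: events are drops of
  the clean PPGamp below the mean of the preceding 15-second baseline; each
  event's value is `(drop area / duration) / baseline`, summarised as the
  nightly median.
- **PPGampCV** — coefficient of variation (SD/mean) of PPGamp over a
  5-minute sliding window stepped every 30 seconds; a rule-free surrogate
  for Mvasoc.

It also synchronises unaligned finger/wrist recordings by maximum positive
cross-correlation within a ±30 s window (with an autocorrelation noise
check) and reproduces the validation statistics: within-device
Mvasoc↔PPGampCV correlations (overnight and per-segment peak), across-device
PPGampCV correlations with a ≥3-events-per-segment inclusion rule, and the
regression of nightly median Mvasoc on nightly median PPGampCV.

Because no clinical recordings ship with the package, a seeded synthetic
generator (`vasowave.synthetic_data`) produces paired finger/wrist nights
with known ground truth — injected vasoconstriction events, a shared
vasomotor drive, device-specific gain/noise, a clock offset, hourly sync
pauses and motion artifacts — so the whole pipeline is testable offline.

## Pipeline stages

| Stage | Module | What it does |
|---|---|---|
| simulate | `synthetic_data` | paired nights + ground truth fixtures |
| ingest | `ppg_io` | CSV/EDF → uniform-grid `PPGRecord` with gap mask |
| extract | `pulse_extraction` | beat detection → PPGamp on a 0.5 s grid |
| preprocess | `preprocess` | 15-min segments; loss/motion gate; P98 cap; P95 normalisation; linear detrend; zero-phase low-pass < 0.15 Hz |
| markers | `vasomarkers` | Mvasoc events, sliding-window CV, nightly medians |
| align | `alignment` | ±30 s lag search, autocorrelation check |
| validate | `validation_analysis` | within/across-device correlation reports, nightly-medians regression |

## CLI

Every stage is a subcommand; `run` chains them end to end on simulated data:

```sh
vasowave run --config configs/demo.yaml --out results/demo
```

which writes `nightly_summary.csv`, `within_device.csv`, `across_device.csv`,
`events.csv`, `cv.csv` and a `manifest.json` (config hash, seed, versions).
Reruns with the same config and seed are byte-identical.

Stage-by-stage on files:

```sh
vasowave simulate --config configs/demo.yaml --out sim/
vasowave ingest --edf sim/night01/finger.edf --channel PPG --out finger.archive.csv
vasowave ingest --csv sim/night01/wrist.csv --out wrist.archive.csv
vasowave extract --in finger.archive.csv --out finger.amp.csv
vasowave preprocess --in finger.amp.csv --out finger.clean/
vasowave events --in finger.clean/ --out events.csv
vasowave cv --in finger.clean/ --out cv.csv
vasowave align --finger finger.clean/ --wrist wrist.clean/ --out align.csv
vasowave validate --finger finger.clean/ --wrist wrist.clean/ --out report/
```

All analysis constants (segment length 900 s, cap percentile 98, norm
percentile 95, cutoff 0.15 Hz, baseline 15 s, CV window 300 s / step 30 s,
lag window ±30 s, ≥3-event rule) live in `RunConfig` and can be overridden
via a YAML config. The pivotal free parameters of event detection — the
drop threshold (default 15% below baseline) and minimum duration (3 s) —
are likewise config-exposed.

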