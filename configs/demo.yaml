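# Demo run: 3 simulated 2-hour nights at paper-like event density.
# vasowave run --config configs/demo.yaml --out results/demo
seed: 42
n_nights: 3
simulate:
  duration_s: 7200.0
  event_rate_per_h: 24.0
  event_depth_mean: 0.45
  pulse_rate_bpm: 65.0
  finger_sample_rate: 50.0
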