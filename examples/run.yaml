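# Demo configuration for `burstpause run --config examples/run.yaml --out demo/`
# All analysis parameters shown are the pipeline defaults.
seed: 7
n_trials: 20
max_us: 6
gain_pct_per_us: 6.0      # Ca2+ amplitude gained per embedded burst-pause event (%)
amplitude_noise_pct: 2.0
window_ms: 400.0          # sliding rate window
sigma_ms: 25.0            # density kernel
isi1_max_ms: 9.0          # US first-interval bound
isi2_min_ms: 20.0         # US second-interval (pause) bound
transient_threshold_pct: 10.0
protocol:
  kind: IR
  onset: 2.0
  duration: 1.0
  power: 40.0
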