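# Heart-sound-like synthetic record: Gaussian-enveloped 40 Hz bursts,
# 100 ms wide, every 500 ms, at 1000 Hz. Noise-free by default.
spec:
  fs: 1000
  duration_s: 20.0
  cycle_ms: 500
  cycle_jitter_frac: 0.03
  event_width_ms: 100
  event_shape: burst
  event_amplitude: 1.0
  noise_std: 0.0
  baseline_amp: 0.0
  baseline_hz: 0.3
  seed: 2
params:
  F1_hz: 0
  F2_hz: 60
  W1_ms: 100
  W2_ms: 200
  beta: 0.03
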