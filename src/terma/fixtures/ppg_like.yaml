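# PPG-like synthetic record: smooth Gaussian systolic-style pulses,
# 110 ms wide, every 900 ms, at 200 Hz. Noise-free by default.
spec:
  fs: 200
  duration_s: 20.0
  cycle_ms: 900
  cycle_jitter_frac: 0.03
  event_width_ms: 110
  event_shape: gaussian
  event_amplitude: 1.0
  noise_std: 0.0
  baseline_amp: 0.0
  baseline_hz: 0.3
  seed: 1
params:
  F1_hz: 0.5
  F2_hz: 8
  W1_ms: 110
  W2_ms: 660
  beta: 0.02
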