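# QRS-like synthetic record: biphasic (derivative-of-Gaussian) pulses,
# 80 ms wide, one per second, at 360 Hz. Noise-free by default.
spec:
  fs: 360
  duration_s: 20.0
  cycle_ms: 1000
  cycle_jitter_frac: 0.03
  event_width_ms: 80
  event_shape: biphasic
  event_amplitude: 1.0
  noise_std: 0.0
  baseline_amp: 0.0
  baseline_hz: 0.3
  seed: 0
params:
  F1_hz: 8
  F2_hz: 20
  W1_ms: 80
  W2_ms: 480
  beta: 0.08
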