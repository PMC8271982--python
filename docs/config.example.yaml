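# Example skelact configuration. Unknown keys are rejected at load.
# Validated against docs/config.schema.json (generated from the
# AppConfig pydantic model).

paths:
  data: data
  models: models
  reports: reports

# joint ordering used for encoding (B1..B6, C2..C5, or user-registered)
ordering: B1

# streaming / windowing
window_length: 32   # frames per encoded image
window_stride: 1    # frames between consecutive windows

# overrides of the training recipe (unset keys keep the defaults:
# 200 epochs, batch 64, lr 0.01 stepped /10 every 50 epochs,
# momentum 0.9, weight decay 1e-4, 20 runs)
training:
  epochs: 200
  runs: 20

# overrides of the synthetic collection protocol
protocol:
  n_subjects: 32
  n_frames: 64
  sigma: 0.01   # sensor noise s.d. in meters, at most 0.02

log_level: INFO
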