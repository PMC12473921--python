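# Default pipeline parameters (quoted at 128 Hz; frame lengths rescale
# with the sampling rate).
filter:
  turn: {low_hz: 1.0, high_hz: 50.0, order: 4}
  event: {low_hz: 1.0, high_hz: 50.0, order: 4}
sg:
  turn: {polyorder: 2, frame: 1101}
  event: {polyorder: 50, frame: 801}
median:
  order: 10
segmentation:
  min_turn_s: 1.0
  merge_gap_s: 0.5
  min_walk_s: 2.0
  expected_turn_count: null
events:
  first_side: right
stats:
  alpha: 0.05
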